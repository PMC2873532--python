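"""Machine-readable summaries: fit-vs-empirical curves and sensitivity tables.

The canonical outputs are plain data structures (grids, DataFrames, JSON);
plots are optional side-effects layered on top so downstream checks never
parse images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import SpikeInEvaluation
from .mixture import CutoffRule, MixtureFit, on_density
from .stats import z_transform

__all__ = ["FitReport", "build_fit_report", "sensitivity_table",
           "save_fit_report", "plot_fit_report"]


@dataclass
class FitReport:
    """Grid evaluation of a fitted mixture against its data.

    Component curves are weight-carrying: ``off_pdf`` is xi * Normal pdf and
    ``on_pdf`` is (1 - xi) * convolution pdf, so they sum to ``pdf``.
    ``cutoff_z`` is the score of the integer cutoff count,
    z(x_c, J) — the vertical marker of the fit figures.
    """

    grid: np.ndarray = field(repr=False)
    empirical_cdf: np.ndarray = field(repr=False)
    pdf: np.ndarray = field(repr=False)
    cdf: np.ndarray = field(repr=False)
    off_pdf: np.ndarray = field(repr=False)
    on_pdf: np.ndarray = field(repr=False)
    params: tuple[float, float, float, float]
    level: float
    j: int
    x_c: int
    cutoff_z: float
    n_obs: int

    def ks_distance(self) -> float:
        """Sup distance between model and empirical CDF on the grid."""
        return float(np.max(np.abs(self.cdf - self.empirical_cdf)))


def build_fit_report(z_values, fit: MixtureFit, cutoff: CutoffRule, j: int,
                     grid_size: int = 512) -> FitReport:
    """Evaluate empirical and fitted curves on a common grid.

    Refuses unconverged fits: a report of a non-maximum would be
    misleading.
    """
    if not fit.converged:
        raise ValueError("refusing to report an unconverged fit")
    if grid_size < 16:
        raise ValueError("grid_size must be >= 16")
    z = np.sort(np.asarray(z_values, dtype=float))
    p = fit.params
    lo = min(z.min(), -4.0 * p.sigma) - 0.5
    hi = max(z.max(), p.mu * 4.0) + 0.5
    grid = np.linspace(lo, hi, grid_size)

    emp = np.searchsorted(z, grid, side="right") / z.size
    off_pdf = p.xi * sps.norm.pdf(grid, scale=p.sigma)
    on_pdf = (1.0 - p.xi) * on_density(grid, p)
    pdf = off_pdf + on_pdf
    # model CDF: closed-form Off part + cumulative quadrature of the On part
    on_cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (on_pdf[1:] + on_pdf[:-1]) * np.diff(grid))])
    cdf = p.xi * sps.norm.cdf(grid, scale=p.sigma) + on_cdf
    cdf = np.clip(cdf, 0.0, 1.0)

    x_c = cutoff.x_c(j)
    cutoff_z = z_transform(min(x_c, j), j) if x_c <= j else np.inf
    return FitReport(
        grid=grid, empirical_cdf=emp, pdf=pdf, cdf=cdf,
        off_pdf=off_pdf, on_pdf=on_pdf,
        params=p.as_tuple(), level=cutoff.level, j=int(j), x_c=int(x_c),
        cutoff_z=float(cutoff_z), n_obs=int(z.size),
    )


def sensitivity_table(ev: SpikeInEvaluation) -> pd.DataFrame:
    """Detected fraction per positive spike-in concentration and method."""
    if ev.sensitivity.empty:
        raise ValueError("evaluation contains no positive concentrations")
    return ev.sensitivity.copy()


def save_fit_report(report: FitReport, path) -> None:
    payload = {
        "params": {k: v for k, v in zip(("mu", "alpha", "xi", "sigma2"), report.params)},
        "level": report.level,
        "j": report.j,
        "x_c": report.x_c,
        "cutoff_z": report.cutoff_z if np.isfinite(report.cutoff_z) else None,
        "n_obs": report.n_obs,
        "ks_distance": report.ks_distance(),
        "grid": report.grid.tolist(),
        "empirical_cdf": report.empirical_cdf.tolist(),
        "pdf": report.pdf.tolist(),
        "cdf": report.cdf.tolist(),
        "off_pdf": report.off_pdf.tolist(),
        "on_pdf": report.on_pdf.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def plot_fit_report(report: FitReport, path=None):
    """Density and CDF panels with component curves and the cutoff marker."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(report.grid, np.gradient(report.empirical_cdf, report.grid),
             color="tab:brown", lw=0.8, label="empirical")
    ax1.plot(report.grid, report.pdf, color="tab:green", label="mixture")
    ax1.plot(report.grid, report.off_pdf, color="tab:blue", label="Off")
    ax1.plot(report.grid, report.on_pdf, color="tab:pink", label="On")
    ax2.plot(report.grid, report.empirical_cdf, color="tab:brown", label="empirical")
    ax2.plot(report.grid, report.cdf, color="tab:green", label="model")
    for ax in (ax1, ax2):
        if np.isfinite(report.cutoff_z):
            ax.axvline(report.cutoff_z, ls=":", color="k")
        ax.set_xlabel("z")
        ax.legend(frameon=False)
    ax1.set_ylabel("density")
    ax2.set_ylabel("CDF")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
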