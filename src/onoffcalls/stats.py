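"""The PM>MM order statistic X and its continuous logit transform Z.

For a probe set with J probe pairs, X counts the pairs whose perfect-match
intensity strictly exceeds the mismatch intensity.  Under an unexpressed
gene PM and MM are exchangeable, so X ~ Binomial(J, 1/2); an expressed gene
pushes X towards J.  The transform

    Z = log((X + 1/2) / (J - X + 1/2))

is the empirical logit of X out of J + 1: finite at X = 0 and X = J,
antisymmetric about X = J/2, and centred at 0 for an unexpressed gene, which
is what lets the mixture model treat the 'Off' component as Normal noise
around zero.  Both statistics depend on the intensities only through the
per-pair order relationship, so any strictly increasing rescaling of the
raw intensities leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe_io import ProbeLevelDataset

__all__ = ["XMatrix", "ZMatrix", "count_pm_gt_mm", "z_transform",
           "compute_x_matrix", "compute_z_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class XMatrix:
    """PM>MM counts per (probeset, sample) with the per-cell pair count J.

    ``j`` is a full matrix rather than one value per probe set because rows
    dropped at read time (non-strict validation) can leave a probe set with
    fewer usable pairs in some samples.
    """

    x: pd.DataFrame
    j: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.x.index.equals(self.j.index) or not self.x.columns.equals(self.j.columns):
            raise ValueError("x and j must share index and columns")
        valid = self.j.to_numpy() >= 1
        xv = self.x.to_numpy()
        if np.any((xv < 0) | (xv > self.j.to_numpy())):
            raise ValueError("x out of range [0, j]")
        if not valid.all():
            logger.warning("%d probeset/sample cells have no usable probe pairs",
                           int((~valid).sum()))

    @property
    def j_nominal(self) -> pd.Series:
        """Largest pair count observed per probe set."""
        return self.j.max(axis=1)


@dataclass
class ZMatrix:
    """Logit scores per (probeset, sample); NaN where no pairs were usable."""

    z: pd.DataFrame
    j: pd.DataFrame


def count_pm_gt_mm(pm, mm) -> int:
    """Number of probe pairs with PM strictly greater than MM.

    Ties contribute zero (strict inequality).
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape:
        raise ValueError(f"length mismatch: {pm.shape} vs {mm.shape}")
    if pm.size == 0:
        raise ValueError("empty probe-pair vectors")
    if not (np.all(np.isfinite(pm)) and np.all(np.isfinite(mm))):
        raise ValueError("intensities must be finite")
    if np.any(pm < 0) or np.any(mm < 0):
        raise ValueError("intensities must be nonnegative")
    return int(np.sum(pm > mm))


def z_transform(x, j):
    """Z = log((x + 1/2) / (j - x + 1/2)); finite for all 0 <= x <= j."""
    x_arr = np.asarray(x, dtype=float)
    j_arr = np.asarray(j, dtype=float)
    if np.any(j_arr < 1):
        raise ValueError("j must be >= 1")
    if np.any((x_arr < 0) | (x_arr > j_arr)):
        raise ValueError("x out of range [0, j]")
    out = np.log((x_arr + 0.5) / (j_arr - x_arr + 0.5))
    return float(out) if np.asarray(x).ndim == 0 and np.asarray(j).ndim == 0 else out


def compute_x_matrix(data: ProbeLevelDataset) -> XMatrix:
    """Vectorized X over all probe sets and samples."""
    tab = data.table
    gt = tab["pm"].to_numpy() > tab["mm"].to_numpy()
    grouped = (
        pd.DataFrame({
            "probeset_id": tab["probeset_id"].to_numpy(),
            "sample_id": tab["sample_id"].to_numpy(),
            "gt": gt.astype(int),
        })
        .groupby(["probeset_id", "sample_id"], sort=False, observed=True)
        .agg(x=("gt", "sum"), j=("gt", "size"))
        .reset_index()
    )
    x = grouped.pivot(index="probeset_id", columns="sample_id", values="x")
    j = grouped.pivot(index="probeset_id", columns="sample_id", values="j")
    x = x.reindex(index=data.probeset_ids, columns=data.sample_ids)
    j = j.reindex(index=data.probeset_ids, columns=data.sample_ids)
    x = x.fillna(0).astype(int)
    j = j.fillna(0).astype(int)
    x.index.name = j.index.name = "probeset_id"
    x.columns.name = j.columns.name = "sample_id"
    return XMatrix(x=x, j=j)


def compute_z_matrix(xm: XMatrix) -> ZMatrix:
    """Elementwise logit transform of an X matrix; NaN where j == 0."""
    xv = xm.x.to_numpy(dtype=float)
    jv = xm.j.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        zv = np.log((xv + 0.5) / (jv - xv + 0.5))
    zv = np.where(jv >= 1, zv, np.nan)
    z = pd.DataFrame(zv, index=xm.x.index, columns=xm.x.columns)
    return ZMatrix(z=z, j=xm.j.copy())
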