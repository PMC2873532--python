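"""On/Off calls, per-group probabilities of 'On', and spike-in evaluation.

A call thresholds the PM>MM count: 'On' when X >= x_c for the probe set's
pair count J, where x_c comes from the fitted noise variance through the
tail rule (:class:`~onoffcalls.mixture.CutoffRule`).  Group-level
probabilities average the per-sample posterior Pr(On) under the group's own
fitted mixture; the product of per-sample Pr(Off) — the probability of a
gene being uniformly Off across a group's arrays — is carried alongside
because the candidate-selection procedure ranks on it.

Spike-in evaluation treats 0 pM entries as negative controls and entries at
or above a concentration threshold (default 0.25 pM) as positives.  For
detection (P/M/A) calls, "detected" means Present only; Marginal entries
count neither as detected nor as false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mixture import CutoffRule, MixtureParams, posterior_on
from .stats import XMatrix, ZMatrix

__all__ = ["CallMatrix", "GroupPrOn", "SpikeInEvaluation",
           "make_calls", "group_pr_on", "evaluate_spikein",
           "spikein_counts_from_calls"]


@dataclass
class CallMatrix:
    """Binary On/Off labels per (probeset, sample) plus the cutoffs used."""

    calls: pd.DataFrame
    x_c: dict[int, int]
    provenance: str | None = None

    def on_mask(self) -> pd.DataFrame:
        return self.calls == "On"


@dataclass
class GroupPrOn:
    """Per-group probabilities of the 'On' state.

    pr_on : mean posterior Pr(On) over the group's samples (probeset x group)
    pr_off_uniform : product of per-sample Pr(Off) (probeset x group)
    group_sizes : samples per group
    """

    pr_on: pd.DataFrame
    pr_off_uniform: pd.DataFrame
    group_sizes: dict[str, int]


@dataclass
class SpikeInEvaluation:
    """Per-concentration counts and the derived error rates.

    counts : DataFrame indexed by concentration (pM); per method ``m``,
        columns ``{m}_detected`` / ``{m}_undetected`` (plus ``{m}_marginal``
        for detection calls) and ``{m}_total``.
    fpr, fnr : method -> (numerator, denominator, rate)
    sensitivity : DataFrame, per positive concentration, detected fraction
        per method.
    """

    counts: pd.DataFrame
    fpr: dict[str, tuple[int, int, float]]
    fnr: dict[str, tuple[int, int, float]]
    sensitivity: pd.DataFrame
    n_negative: int
    n_positive: int
    positive_threshold: float


def make_calls(x: XMatrix, cutoffs: CutoffRule | Mapping[int, int],
               provenance: str | None = None) -> CallMatrix:
    """Threshold an X matrix into On/Off labels.

    ``cutoffs`` is either a fitted cutoff rule (evaluated at each J present)
    or an explicit {J: x_c} mapping, which must cover every J in the data.
    """
    jv = x.j.to_numpy()
    js = sorted(set(int(j) for j in np.unique(jv) if j >= 1))
    if isinstance(cutoffs, CutoffRule):
        table = cutoffs.x_c_table(js)
    else:
        table = {int(k): int(v) for k, v in dict(cutoffs).items()}
        missing = [j for j in js if j not in table]
        if missing:
            raise KeyError(f"no cutoff provided for probe-pair counts {missing}")
    xc = np.zeros_like(jv)
    for j in js:
        xc[jv == j] = table[j]
    on = (x.x.to_numpy() >= xc) & (jv >= 1)
    calls = pd.DataFrame(np.where(on, "On", "Off"),
                         index=x.x.index, columns=x.x.columns)
    return CallMatrix(calls=calls, x_c={j: table[j] for j in js}, provenance=provenance)


def group_pr_on(z: ZMatrix, fits: Mapping[str, MixtureParams],
                groups: Mapping[str, str]) -> GroupPrOn:
    """Mean posterior Pr(On) and uniform-Off probability per group.

    ``groups`` maps each sample id to a group name; each group needs its own
    fitted parameters in ``fits``.
    """
    samples = list(z.z.columns)
    unmapped = [s for s in samples if s not in groups]
    if unmapped:
        raise KeyError(f"samples without a group: {unmapped[:5]}")
    by_group: dict[str, list[str]] = {}
    for s in samples:
        by_group.setdefault(groups[s], []).append(s)
    for g, members in by_group.items():
        if g not in fits:
            raise KeyError(f"no fitted parameters for group {g!r}")
        if not members:
            raise ValueError(f"empty group {g!r}")

    pr_on = {}
    pr_off_uniform = {}
    for g, members in by_group.items():
        params = fits[g]
        zvals = z.z[members].to_numpy()
        post = np.full(zvals.shape, np.nan)
        ok = np.isfinite(zvals)
        post[ok] = posterior_on(zvals[ok], params)
        pr_on[g] = np.nanmean(post, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_off = np.where(ok, np.log1p(-np.clip(post, 0.0, 1.0)), 0.0)
        pr_off_uniform[g] = np.exp(log_off.sum(axis=1))
    idx = z.z.index
    return GroupPrOn(
        pr_on=pd.DataFrame(pr_on, index=idx),
        pr_off_uniform=pd.DataFrame(pr_off_uniform, index=idx),
        group_sizes={g: len(m) for g, m in by_group.items()},
    )


def spikein_counts_from_calls(calls: pd.DataFrame, truth: pd.DataFrame,
                              method: str = "onoff") -> pd.DataFrame:
    """Aggregate a label matrix into per-concentration counts.

    ``truth`` has columns probeset_id, sample_id, concentration_pM; every
    (probeset, sample) it names must be present in ``calls``.
    """
    need = {"probeset_id", "sample_id", "concentration_pM"}
    if not need <= set(truth.columns):
        raise ValueError(f"truth table needs columns {sorted(need)}")
    rows = []
    for _, rec in truth.iterrows():
        try:
            label = calls.at[rec["probeset_id"], rec["sample_id"]]
        except KeyError as exc:
            raise KeyError(
                f"no call for ({rec['probeset_id']}, {rec['sample_id']})"
            ) from exc
        rows.append((float(rec["concentration_pM"]), label))
    df = pd.DataFrame(rows, columns=["concentration_pM", "label"])
    if df["label"].isin(["On", "Off"]).all():
        out = pd.crosstab(df["concentration_pM"], df["label"])
        out = out.reindex(columns=["On", "Off"], fill_value=0)
        out.columns = [f"{method}_detected", f"{method}_undetected"]
    elif df["label"].isin(["P", "M", "A"]).all():
        out = pd.crosstab(df["concentration_pM"], df["label"])
        out = out.reindex(columns=["P", "M", "A"], fill_value=0)
        out.columns = [f"{method}_detected", f"{method}_marginal", f"{method}_undetected"]
    else:
        raise ValueError("mixed or unknown label sets in calls")
    out[f"{method}_total"] = out.sum(axis=1)
    out.index.name = "concentration_pM"
    return out


def evaluate_spikein(counts: pd.DataFrame | None = None, *,
                     calls: CallMatrix | pd.DataFrame | None = None,
                     truth: pd.DataFrame | None = None,
                     detection_calls: pd.DataFrame | None = None,
                     positive_threshold: float = 0.25) -> SpikeInEvaluation:
    """Spike-in error rates from counts or from call matrices plus truth.

    Supply either ``counts`` (per-concentration table as produced by
    :func:`spikein_counts_from_calls`, methods side by side) or ``calls`` +
    ``truth`` (and optionally ``detection_calls`` with P/M/A labels).

    Negatives are the 0 pM entries; positives are entries with
    concentration >= ``positive_threshold``.  False positive rate is the
    detected fraction among negatives; false negative rate is the
    undetected fraction among positives (Marginal detection calls are
    excluded from the false-negative numerator).
    """
    if counts is None:
        if calls is None or truth is None:
            raise ValueError("provide either counts or calls+truth")
        mat = calls.calls if isinstance(calls, CallMatrix) else calls
        counts = spikein_counts_from_calls(mat, truth, method="onoff")
        if detection_calls is not None:
            det = spikein_counts_from_calls(detection_calls, truth, method="mas5")
            counts = counts.join(det, how="outer").fillna(0).astype(int)
    counts = counts.sort_index()
    conc = counts.index.to_numpy(dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc < 0):
        raise ValueError("unknown or negative concentration in counts index")
    neg = conc == 0.0
    pos = conc >= positive_threshold

    methods = sorted({c.rsplit("_", 1)[0] for c in counts.columns})
    fpr: dict[str, tuple[int, int, float]] = {}
    fnr: dict[str, tuple[int, int, float]] = {}
    sens_cols = {}
    n_negative = n_positive = 0
    for m in methods:
        det = counts[f"{m}_detected"].to_numpy()
        undet = counts[f"{m}_undetected"].to_numpy()
        total = counts[f"{m}_total"].to_numpy()
        n_neg = int(total[neg].sum())
        n_pos = int(total[pos].sum())
        n_negative, n_positive = n_neg, n_pos
        fp = int(det[neg].sum())
        fn = int(undet[pos].sum())
        fpr[m] = (fp, n_neg, fp / n_neg if n_neg else np.nan)
        fnr[m] = (fn, n_pos, fn / n_pos if n_pos else np.nan)
        with np.errstate(invalid="ignore"):
            sens_cols[m] = det[pos] / total[pos]
    sensitivity = pd.DataFrame(sens_cols, index=counts.index[pos])
    sensitivity.index.name = "concentration_pM"
    return SpikeInEvaluation(
        counts=counts, fpr=fpr, fnr=fnr, sensitivity=sensitivity,
        n_negative=n_negative, n_positive=n_positive,
        positive_threshold=positive_threshold,
    )
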