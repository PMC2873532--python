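"""Logical genotype-phenotype gene types and the OR_On candidate screen.

A gene's On/Off state can relate to a binary outcome (R+ adverse, R-
benign) as a logic gate.  With a 2x2 table of states by outcomes, the four
archetypes are characterised by one empty cell:

    OR_On   : no On gene in any R- case      (On is sufficient for R+)
    OR_Off  : no Off gene in any R- case     (Off is sufficient for R+)
    AND_On  : no Off gene in any R+ case     (On is necessary for R+)
    AND_Off : no On gene in any R+ case      (Off is necessary for R+)

The OR_On screen mirrors how such genes are found in a two-phenotype
cohort: keep genes uniformly Off in the favorable group but varying in the
unfavorable group, shortlist those most confidently uniformly Off in the
favorable group, then rank by the gap in the group probabilities of being
On.  A SAM-style relative-difference statistic on expression intensities is
provided as the intensity-based comparator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import CallMatrix, GroupPrOn

__all__ = ["LogicContingency", "classify_logic_type", "contingency_from_states",
           "rank_by_pr_on_difference", "select_or_on",
           "relative_difference", "relative_difference_table"]

LOGIC_TYPES = ("OR_On", "OR_Off", "AND_On", "AND_Off")


@dataclass(frozen=True)
class LogicContingency:
    """2x2 counts of gene state (g+/g-) by outcome (R+/R-)."""

    n_gplus_rplus: int
    n_gplus_rminus: int
    n_gminus_rplus: int
    n_gminus_rminus: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    @property
    def n1(self) -> int:
        """Column total for R+."""
        return self.n_gplus_rplus + self.n_gminus_rplus

    @property
    def n2(self) -> int:
        """Column total for R-."""
        return self.n_gplus_rminus + self.n_gminus_rminus


def classify_logic_type(t: LogicContingency, tolerance: int = 0) -> str:
    """Label a contingency table as one of the four logic types or 'none'.

    ``tolerance`` relaxes the empty-cell requirement to at most that many
    counts.  When several patterns hold, the fixed priority
    OR_On > OR_Off > AND_On > AND_Off applies.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if t.n_gplus_rminus <= tolerance and t.n_gplus_rplus > 0:
        return "OR_On"
    if t.n_gminus_rminus <= tolerance and t.n_gminus_rplus > 0:
        return "OR_Off"
    if t.n_gminus_rplus <= tolerance and t.n_gplus_rplus > 0:
        return "AND_On"
    if t.n_gplus_rplus <= tolerance and t.n_gminus_rplus > 0:
        return "AND_Off"
    return "none"


def contingency_from_states(on_states: Mapping[str, bool] | pd.Series,
                            groups: Mapping[str, str],
                            adverse: str = "unfavorable") -> LogicContingency:
    """Build the 2x2 table for one gene from per-sample On states.

    ``adverse`` names the group playing the R+ role; every other group is
    pooled into R-.
    """
    s = pd.Series(on_states)
    a = b = c = d = 0
    for sample, on in s.items():
        rplus = groups[sample] == adverse
        if on and rplus:
            a += 1
        elif on:
            b += 1
        elif rplus:
            c += 1
        else:
            d += 1
    return LogicContingency(a, b, c, d)


def rank_by_pr_on_difference(pr_on_fav, pr_on_unfav, genes=None) -> pd.DataFrame:
    """Rank genes by Pr_On(unfavorable) - Pr_On(favorable), descending.

    Ties break by gene identifier.  Returns columns
    gene, pr_on_fav, pr_on_unfav, diff, rank (1 = largest diff).
    """
    fav = np.asarray(pr_on_fav, dtype=float)
    unfav = np.asarray(pr_on_unfav, dtype=float)
    if fav.shape != unfav.shape:
        raise ValueError("group probability vectors must have equal length")
    if genes is None:
        genes = [f"g{i}" for i in range(fav.size)]
    df = pd.DataFrame({"gene": list(genes), "pr_on_fav": fav,
                       "pr_on_unfav": unfav, "diff": unfav - fav})
    df = df.sort_values(["diff", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def select_or_on(pron: GroupPrOn, calls: CallMatrix,
                 groups: Mapping[str, str], *,
                 favorable: str = "favorable", unfavorable: str = "unfavorable",
                 top_n: int = 100) -> pd.DataFrame:
    """Three-step OR_On candidate screen.

    1. Per-group probabilities of 'On' come in via ``pron`` (posterior
       means and the uniform-Off products under each group's fit).
    2. Filter to genes with no On call among favorable samples, and both an
       On and an Off call among unfavorable samples.
    3. Shortlist the ``top_n`` genes with the largest probability of being
       uniformly Off in the favorable group, then rank the shortlist by
       Pr_On(unfavorable) - Pr_On(favorable), descending (ties by gene id).

    Returns columns gene, pr_on_fav, pr_on_unfav, pr_off_uniform_fav, diff,
    rank.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    for g in (favorable, unfavorable):
        if g not in pron.pr_on.columns:
            raise KeyError(f"group {g!r} missing from group probabilities")

    on = calls.on_mask()
    fav_samples = [s for s in on.columns if groups.get(s) == favorable]
    unfav_samples = [s for s in on.columns if groups.get(s) == unfavorable]
    if not fav_samples or not unfav_samples:
        raise ValueError("both favorable and unfavorable samples are required")

    uniformly_off_fav = ~on[fav_samples].any(axis=1)
    varying_unfav = on[unfav_samples].any(axis=1) & (~on[unfav_samples]).any(axis=1)
    g1 = on.index[uniformly_off_fav & varying_unfav]

    shortlist = (
        pron.pr_off_uniform.loc[g1, favorable]
        .sort_values(ascending=False, kind="mergesort")
        .head(top_n)
        .index
    )
    ranked = rank_by_pr_on_difference(
        pron.pr_on.loc[shortlist, favorable].to_numpy(),
        pron.pr_on.loc[shortlist, unfavorable].to_numpy(),
        genes=list(shortlist),
    )
    ranked.insert(3, "pr_off_uniform_fav",
                  pron.pr_off_uniform.loc[ranked["gene"], favorable].to_numpy())
    return ranked


def _sam_scale(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pooled standard error of the mean difference (the SAM 's')."""
    n1, n2 = v1.size, v2.size
    ss = np.sum((v1 - v1.mean()) ** 2) + np.sum((v2 - v2.mean()) ** 2)
    return float(np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2)))


def relative_difference(values_group1, values_group2, s0: float = 0.0) -> float:
    """Moderated mean-difference statistic d = (mean2 - mean1) / (s + s0).

    ``s`` is the pooled standard error of the difference of means; ``s0``
    is the stabilizing constant added to keep small-variance genes from
    dominating.  Use :func:`relative_difference_table` for the gene-wise
    version with the median-``s`` default.
    """
    v1 = np.asarray(values_group1, dtype=float)
    v2 = np.asarray(values_group2, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise ValueError("need at least 2 samples per group")
    s = _sam_scale(v1, v2)
    if s + s0 == 0:
        raise ZeroDivisionError("zero variance with s0 = 0")
    return (float(v2.mean()) - float(v1.mean())) / (s + s0)


def relative_difference_table(matrix_group1: pd.DataFrame,
                              matrix_group2: pd.DataFrame,
                              s0: float | str = "auto") -> pd.DataFrame:
    """Gene-wise relative differences for genes x samples matrices.

    With ``s0='auto'``, the stabilizer is the median of the per-gene pooled
    standard errors.  Returns columns d, s, rank (descending d).
    """
    if not matrix_group1.index.equals(matrix_group2.index):
        raise ValueError("gene indexes must match")
    m1 = matrix_group1.to_numpy(dtype=float)
    m2 = matrix_group2.to_numpy(dtype=float)
    if m1.shape[1] < 2 or m2.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    n1, n2 = m1.shape[1], m2.shape[1]
    ss = (np.sum((m1 - m1.mean(axis=1, keepdims=True)) ** 2, axis=1)
          + np.sum((m2 - m2.mean(axis=1, keepdims=True)) ** 2, axis=1))
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    s0_val = float(np.median(s)) if s0 == "auto" else float(s0)
    d = (m2.mean(axis=1) - m1.mean(axis=1)) / (s + s0_val)
    out = pd.DataFrame({"d": d, "s": s}, index=matrix_group1.index)
    out["rank"] = out["d"].rank(ascending=False, method="first").astype(int)
    return out
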