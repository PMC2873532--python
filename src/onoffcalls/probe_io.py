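"""Reading, validating and writing probe-level PM/MM tables and call tables.

The canonical probe-level format is a long delimited text table (TSV by
default, CSV by extension) with header columns

    probeset_id, probe_pair_index, sample_id, pm, mm

one row per (probe set, probe pair, sample).  ``probe_pair_index`` is
1-based within a probe set; intensities are nonnegative fluorescence values
on any positive scale — the downstream statistic is rank-based per pair, so
no normalization is required or performed.  Conversion from vendor binary
files is the caller's concern (any CEL reader that can emit this five-column
table will do).

Call tables are wide: a ``probeset_id`` column followed by one column per
sample, cells in {P, M, A} (detection calls) or {On, Off}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeLevelDataset",
    "ProbeTableFormatError",
    "ProbeValidationError",
    "read_probe_table",
    "write_probe_table",
    "read_calls_table",
    "write_calls_table",
    "REQUIRED_COLUMNS",
    "VALID_CALL_LABELS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("probeset_id", "probe_pair_index", "sample_id", "pm", "mm")
VALID_CALL_LABELS = frozenset({"P", "M", "A", "On", "Off"})


class ProbeTableFormatError(ValueError):
    """Malformed file structure (missing columns, unparseable header)."""


class ProbeValidationError(ValueError):
    """Structurally valid file whose contents violate the data contract."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ProbeLevelDataset:
    """Validated long-format PM/MM intensities.

    ``table`` holds one row per (probeset, pair, sample), sorted by probe
    set (first appearance), pair index, then sample (first appearance).
    ``sample_ids`` / ``probeset_ids`` preserve first-appearance order.
    """

    table: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)
    probeset_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ProbeTableFormatError(f"missing required columns: {missing}")
        if not self.sample_ids:
            self.sample_ids = list(pd.unique(self.table["sample_id"]))
        if not self.probeset_ids:
            self.probeset_ids = list(pd.unique(self.table["probeset_id"]))

    @classmethod
    def from_table(cls, table: pd.DataFrame, *, strict: bool = True,
                   require_consistent_j: bool = True) -> "ProbeLevelDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ProbeTableFormatError(f"missing required columns: {missing}")
        tab = table.loc[:, list(REQUIRED_COLUMNS)].copy()
        tab["probeset_id"] = tab["probeset_id"].astype(str)
        tab["sample_id"] = tab["sample_id"].astype(str)
        try:
            tab["probe_pair_index"] = tab["probe_pair_index"].astype(int)
        except (ValueError, TypeError) as exc:
            raise ProbeTableFormatError(f"non-integer probe_pair_index: {exc}") from exc
        for col in ("pm", "mm"):
            tab[col] = pd.to_numeric(tab[col], errors="coerce")

        bad = ~(np.isfinite(tab["pm"]) & np.isfinite(tab["mm"])
                & (tab["pm"] >= 0) & (tab["mm"] >= 0))
        if bad.any():
            if strict:
                raise ProbeValidationError(
                    f"{int(bad.sum())} rows with negative, NaN or non-numeric intensities"
                )
            logger.warning("dropping %d rows with invalid intensities", int(bad.sum()))
            tab = tab.loc[~bad]
            require_consistent_j = False  # dropped rows may leave ragged J
        if len(tab) and int(tab["probe_pair_index"].min()) < 1:
            raise ProbeValidationError("probe_pair_index must be 1-based (>= 1)")

        sample_order = list(pd.unique(tab["sample_id"]))
        probeset_order = list(pd.unique(tab["probeset_id"]))

        dup = tab.duplicated(subset=["probeset_id", "probe_pair_index", "sample_id"])
        if dup.any():
            raise ProbeValidationError(
                f"{int(dup.sum())} duplicate (probeset, pair, sample) rows"
            )
        if require_consistent_j:
            pairs_per = tab.groupby(["probeset_id", "sample_id"], sort=False)[
                "probe_pair_index"].agg(frozenset)
            n_distinct = pairs_per.groupby(level=0, sort=False).nunique()
            inconsistent = n_distinct[n_distinct > 1]
            if len(inconsistent):
                raise ProbeValidationError(
                    "probe sets with inconsistent probe pairs across samples: "
                    f"{list(inconsistent.index[:5])}"
                )

        tab = tab.sort_values(
            ["probeset_id", "probe_pair_index", "sample_id"],
            key=lambda s: (s.map({v: i for i, v in enumerate(probeset_order)})
                           if s.name == "probeset_id"
                           else s.map({v: i for i, v in enumerate(sample_order)})
                           if s.name == "sample_id" else s),
        ).reset_index(drop=True)
        return cls(table=tab, sample_ids=sample_order, probeset_ids=probeset_order)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    def j(self) -> pd.Series:
        """Nominal probe-pair count per probe set (max over samples)."""
        counts = self.table.groupby(["probeset_id", "sample_id"], sort=False).size()
        return counts.groupby(level=0, sort=False).max().reindex(self.probeset_ids)

    def probe_matrices(self, probeset_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(pm, mm) arrays of shape (J, n_samples) for one probe set.

        Requires consistent pairs across samples; NaN where a sample lacks
        a pair (ragged non-strict datasets).
        """
        sub = self.table[self.table["probeset_id"] == probeset_id]
        if sub.empty:
            raise KeyError(probeset_id)
        pm = sub.pivot(index="probe_pair_index", columns="sample_id", values="pm")
        mm = sub.pivot(index="probe_pair_index", columns="sample_id", values="mm")
        pm = pm.reindex(columns=self.sample_ids)
        mm = mm.reindex(columns=self.sample_ids)
        return pm.to_numpy(), mm.to_numpy()

    def equals(self, other: "ProbeLevelDataset", rtol: float = 1e-9) -> bool:
        if self.sample_ids != other.sample_ids or self.probeset_ids != other.probeset_ids:
            return False
        a, b = self.table, other.table
        if len(a) != len(b):
            return False
        keys = ["probeset_id", "probe_pair_index", "sample_id"]
        if not a[keys].reset_index(drop=True).equals(b[keys].reset_index(drop=True)):
            return False
        return bool(
            np.allclose(a["pm"], b["pm"], rtol=rtol)
            and np.allclose(a["mm"], b["mm"], rtol=rtol)
        )


def read_probe_table(path, *, strict: bool = True) -> ProbeLevelDataset:
    """Read and validate a probe-level table.

    With ``strict=False``, rows with invalid intensities are dropped (count
    logged) and per-sample ragged probe sets are tolerated.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.ParserError as exc:
        raise ProbeTableFormatError(f"unparseable table {path}: {exc}") from exc
    return ProbeLevelDataset.from_table(raw, strict=strict)


def write_probe_table(data: ProbeLevelDataset, path) -> None:
    """Write a dataset in the canonical long format (re-readable)."""
    path = Path(path)
    data.table.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def read_calls_table(path) -> pd.DataFrame:
    """Read a wide probeset x sample label matrix; labels in {P,M,A,On,Off}."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.columns[0] != "probeset_id":
        raise ProbeTableFormatError("first column of a calls table must be 'probeset_id'")
    df = df.set_index("probeset_id")
    unknown = set(df.to_numpy().ravel()) - VALID_CALL_LABELS
    if unknown:
        raise ProbeValidationError(f"unknown call labels: {sorted(unknown)}")
    return df


def write_calls_table(calls: pd.DataFrame, path) -> None:
    path = Path(path)
    unknown = set(calls.to_numpy().ravel()) - VALID_CALL_LABELS
    if unknown:
        raise ProbeValidationError(f"unknown call labels: {sorted(unknown)}")
    out = calls.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep=_sep_for(path))
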