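"""Protein-group table I/O and quality filtering for SILAC ratio data.

A protein-group table is a wide, tab-separated table with one row per
protein group and, for each replicate ``r`` and time point ``t`` (hours),
a positive H/L ratio column ``ratio_r{r}_t{t}`` and an integer evidence
count column ``evidence_r{r}_t{t}``.  ``contaminant`` and ``reverse``
columns use ``+``/``-`` flags.  Ratios are oriented treated/control after
reading (label-swapped replicates are inverted on load).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinGroupTable",
    "FilterReport",
    "read_protein_groups",
    "write_protein_groups",
    "filter_quality",
    "detect_outliers",
    "filter_occurrence",
    "median_log2",
]

_RATIO_RE = re.compile(r"^ratio_r(\d+)_t(\d+)$")


@dataclass
class ProteinGroupTable:
    """Wide protein-group table plus its replicate/time-point layout.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain ``group_ids`` (semicolon-joined accessions),
        ``gene_name``, boolean ``is_contaminant``/``is_reverse`` and the
        ``ratio_r{r}_t{t}`` / ``evidence_r{r}_t{t}`` column grid.
    replicates, timepoints : tuple of int
        Replicate indices (1-based) and time points in hours.
    """

    df: pd.DataFrame
    replicates: tuple[int, ...]
    timepoints: tuple[int, ...]

    def __post_init__(self) -> None:
        self.replicates = tuple(self.replicates)
        self.timepoints = tuple(self.timepoints)
        self.validate()

    # -- column helpers -------------------------------------------------
    def ratio_col(self, r: int, t: int) -> str:
        return f"ratio_r{r}_t{t}"

    def evidence_col(self, r: int, t: int) -> str:
        return f"evidence_r{r}_t{t}"

    def ratio_cols(self, t: int) -> list[str]:
        return [self.ratio_col(r, t) for r in self.replicates]

    def ratios(self, t: int) -> pd.DataFrame:
        """Replicate-by-row ratio block for one time point."""
        return self.df[self.ratio_cols(t)]

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        required = {"group_ids", "gene_name", "is_contaminant", "is_reverse"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        for t in self.timepoints:
            for r in self.replicates:
                for col in (self.ratio_col(r, t), self.evidence_col(r, t)):
                    if col not in self.df.columns:
                        raise ValueError(f"missing column: {col}")
        ids = self.df["group_ids"].astype(str)
        if ids.str.len().eq(0).any():
            raise ValueError("empty group_ids")
        key = ids.map(lambda s: frozenset(s.split(";")))
        if key.duplicated().any():
            dup = ids[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate group id set: {dup}")
        for t in self.timepoints:
            block = self.ratios(t).to_numpy(dtype=float)
            if np.any(block[np.isfinite(block)] <= 0):
                raise ValueError(f"non-positive ratio at t={t}h")

    def id_sets(self) -> pd.Series:
        return self.df["group_ids"].map(lambda s: frozenset(str(s).split(";")))

    def copy(self) -> "ProteinGroupTable":
        return ProteinGroupTable(self.df.copy(), self.replicates, self.timepoints)


@dataclass
class FilterReport:
    """Bookkeeping of the quality-filter cascade; counts are rows."""

    input_rows: int = 0
    removed_contaminant: int = 0
    removed_reverse: int = 0
    removed_lab_list: int = 0
    removed_outlier: int = 0
    removed_no_data: int = 0
    cells_blanked_single_evidence: int = 0
    timepoints_blanked_occurrence: int = 0
    retained: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return (
            self.removed_contaminant
            + self.removed_reverse
            + self.removed_lab_list
            + self.removed_outlier
            + self.removed_no_data
        )

    def check(self) -> None:
        if self.removed + self.retained != self.input_rows:
            raise AssertionError(
                f"report not conserved: {self.removed} + {self.retained} "
                f"!= {self.input_rows}"
            )

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "input_rows",
                "removed_contaminant",
                "removed_reverse",
                "removed_lab_list",
                "removed_outlier",
                "removed_no_data",
                "cells_blanked_single_evidence",
                "timepoints_blanked_occurrence",
                "retained",
            )
        }
        d.update(self.extra)
        return d


def _layout_from_columns(columns) -> tuple[tuple[int, ...], tuple[int, ...]]:
    reps, tps = set(), set()
    for c in columns:
        m = _RATIO_RE.match(c)
        if m:
            reps.add(int(m.group(1)))
            tps.add(int(m.group(2)))
    if not reps:
        raise ValueError("no ratio_r*_t* columns found")
    return tuple(sorted(reps)), tuple(sorted(tps))


def read_protein_groups(path, label_swap_map=()) -> ProteinGroupTable:
    """Read a protein-group TSV, inverting label-swapped replicates.

    Parameters
    ----------
    path : str or pathlib.Path
    label_swap_map : iterable of int
        Replicate indices whose H/L ratios were acquired with inverted
        labels; their ratios are stored as ``1/r`` so that every row ends
        up oriented treated/control.

    Raises
    ------
    ValueError
        On malformed numeric cells, reported with the offending row index.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reps, tps = _layout_from_columns(raw.columns)
    df = pd.DataFrame(index=raw.index)
    df["group_ids"] = raw["group_ids"]
    df["gene_name"] = raw.get("gene_name", "")
    df["is_contaminant"] = raw.get("contaminant", "-").isin(["+", "1", "True", "true"])
    df["is_reverse"] = raw.get("reverse", "-").isin(["+", "1", "True", "true"])
    swap = set(label_swap_map)
    for t in tps:
        for r in reps:
            rcol, ecol = f"ratio_r{r}_t{t}", f"evidence_r{r}_t{t}"
            vals = raw[rcol].mask(raw[rcol] == "", np.nan)
            try:
                ratio = vals.astype(float)
            except ValueError:
                bad = vals[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
                raise ValueError(
                    f"malformed ratio in column {rcol}, row {bad.index[0]}: "
                    f"{bad.iloc[0]!r}"
                ) from None
            if r in swap:
                ratio = 1.0 / ratio
            df[rcol] = ratio
            ev = raw[ecol].replace("", "0") if ecol in raw.columns else "0"
            df[ecol] = pd.to_numeric(ev, errors="raise").astype(int)
    return ProteinGroupTable(df, reps, tps)


def write_protein_groups(table: ProteinGroupTable, path) -> None:
    """Write the on-disk TSV form (``+``/``-`` flags, blank for absent)."""
    out = table.df.copy()
    out["contaminant"] = np.where(out.pop("is_contaminant"), "+", "-")
    out["reverse"] = np.where(out.pop("is_reverse"), "+", "-")
    lead = ["group_ids", "gene_name", "contaminant", "reverse"]
    out = out[lead + [c for c in out.columns if c not in lead]]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def detect_outliers(table: ProteinGroupTable, factor: float = 1.41) -> set:
    """Rows whose replicate ratios disagree by more than ``factor``.

    A row is flagged iff at any time point ``max(ratio)/min(ratio)`` over
    the available replicates exceeds ``factor``.  Rows with fewer than two
    available replicates at a time point cannot be flagged there.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    flagged: set = set()
    for t in table.timepoints:
        block = table.ratios(t).to_numpy(dtype=float)
        n = np.sum(np.isfinite(block), axis=1)
        pair = n >= 2
        if not pair.any():
            continue
        hi = np.nanmax(block[pair], axis=1)
        lo = np.nanmin(block[pair], axis=1)
        bad = np.zeros(len(block), dtype=bool)
        bad[pair] = hi / lo > factor
        flagged.update(table.df.index[bad])
    return flagged


def filter_quality(
    table: ProteinGroupTable,
    lab_contaminant_ids=(),
    outlier_factor: float = 1.41,
    min_evidence: int = 2,
    min_replicates: int = 2,
) -> tuple[ProteinGroupTable, FilterReport]:
    """Apply the quality-filter cascade.

    Steps, in order: drop contaminant and reverse rows and any row whose
    group contains a lab-list accession; blank ratio cells backed by fewer
    than ``min_evidence`` evidences; per time point, blank a row's ratios
    there when present in fewer than ``min_replicates`` replicates; drop
    rows flagged by :func:`detect_outliers`; drop rows left without any
    quantified time point.
    """
    rep = FilterReport(input_rows=len(table))
    df = table.df.copy()

    cont = df["is_contaminant"]
    rep.removed_contaminant = int(cont.sum())
    df = df[~cont]
    rev = df["is_reverse"]
    rep.removed_reverse = int(rev.sum())
    df = df[~rev]
    lab = set(lab_contaminant_ids)
    if lab:
        in_lab = df["group_ids"].map(
            lambda s: bool(lab & set(str(s).split(";")))
        )
        rep.removed_lab_list = int(in_lab.sum())
        df = df[~in_lab]

    # blank single-evidence ratio cells
    for t in table.timepoints:
        for r in table.replicates:
            rcol = f"ratio_r{r}_t{t}"
            ecol = f"evidence_r{r}_t{t}"
            single = df[rcol].notna() & (df[ecol] < min_evidence)
            rep.cells_blanked_single_evidence += int(single.sum())
            df.loc[single, rcol] = np.nan

    # per-time-point replicate occurrence
    for t in table.timepoints:
        cols = [f"ratio_r{r}_t{t}" for r in table.replicates]
        n_present = df[cols].notna().sum(axis=1)
        under = (n_present > 0) & (n_present < min_replicates)
        rep.timepoints_blanked_occurrence += int(under.sum())
        df.loc[under, cols] = np.nan

    working = ProteinGroupTable(df, table.replicates, table.timepoints)
    outliers = detect_outliers(working, outlier_factor)
    rep.removed_outlier = len(outliers)
    df = df.drop(index=list(outliers))

    all_ratio = [c for c in df.columns if _RATIO_RE.match(c)]
    empty = df[all_ratio].isna().all(axis=1)
    rep.removed_no_data = int(empty.sum())
    df = df[~empty]

    rep.retained = len(df)
    rep.check()
    return ProteinGroupTable(df, table.replicates, table.timepoints), rep


def filter_occurrence(table: ProteinGroupTable) -> ProteinGroupTable:
    """Keep rows quantified in every replicate at one or more time points."""
    keep = pd.Series(False, index=table.df.index)
    for t in table.timepoints:
        keep |= table.ratios(t).notna().all(axis=1)
    return ProteinGroupTable(
        table.df[keep].copy(), table.replicates, table.timepoints
    )


def median_log2(table: ProteinGroupTable, timepoint: int) -> pd.Series:
    """Per-row median over available replicates of log2(ratio).

    Rows with no value at ``timepoint`` yield NaN.
    """
    block = table.ratios(timepoint).to_numpy(dtype=float)
    med = np.full(len(block), np.nan)
    any_val = np.isfinite(block).any(axis=1)
    if any_val.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            med[any_val] = np.nanmedian(np.log2(block[any_val]), axis=1)
    return pd.Series(med, index=table.df.index, name=f"median_log2_t{timepoint}")
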