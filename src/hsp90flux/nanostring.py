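"""nCounter processing: background, positive-control QC, geNorm, normalization.

The processing chain is background subtraction (mean + 2 sd of the
negative controls per sample, floor 1), a positive-control ratio gate,
geNorm selection of stable reference genes, normalization of target
counts by the geometric mean of the selected references, and log2
fold-changes of condition geometric means (treated over control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NanoStringDataset",
    "GeNormResult",
    "background_correct",
    "qc_positive_controls",
    "genorm_m_values",
    "genorm_select",
    "normalize_counts",
    "fold_changes",
    "read_counts_csv",
]

NEGATIVE = "neg"
POSITIVE = "pos"
REFERENCE = "ref"
TARGET = "target"
_CLASSES = (NEGATIVE, POSITIVE, REFERENCE, TARGET)


@dataclass
class NanoStringDataset:
    """Counts matrix (probes x samples) with probe classes and conditions.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are probes, columns are samples; non-negative reals.
    probe_class : pandas.Series
        Probe -> one of ``neg``/``pos``/``ref``/``target``.
    condition : pandas.Series
        Sample -> condition label (e.g. ``GA`` / ``DMSO``).
    replicate : pandas.Series, optional
        Sample -> biological replicate id, for technical-sample averaging.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    condition: pd.Series
    replicate: pd.Series | None = None

    def __post_init__(self) -> None:
        if set(self.probe_class.index) != set(self.counts.index):
            raise ValueError("probe_class must cover exactly the count probes")
        if set(self.condition.index) != set(self.counts.columns):
            raise ValueError("condition must cover exactly the count samples")
        bad = set(self.probe_class.unique()) - set(_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.probes(NEGATIVE)) < 2 or len(self.probes(POSITIVE)) < 2:
            raise ValueError("need at least 2 negative and 2 positive controls")

    def probes(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]

    def samples(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return list(self.counts.columns)
        return [s for s in self.counts.columns if self.condition[s] == condition]

    def with_counts(self, counts: pd.DataFrame) -> "NanoStringDataset":
        return NanoStringDataset(counts, self.probe_class, self.condition,
                                 self.replicate)


@dataclass
class GeNormResult:
    """geNorm stability ranking and the selected reference set."""

    m_values: pd.Series           # initial M per candidate
    ranking: list[str]            # most stable first
    selected: list[str]           # the k survivors, input order
    dropped: list[str] = field(default_factory=list)  # least stable first


def background_correct(dataset: NanoStringDataset) -> NanoStringDataset:
    """Subtract mean + 2 sd of each sample's negative controls.

    Applies to non-control probes (references and targets); corrected
    values below 1 are fixed to 1.  Control probes are left untouched.
    """
    neg = dataset.counts.loc[dataset.probes(NEGATIVE)]
    if len(neg) < 2:
        raise ValueError("need >= 2 negative controls for the sd")
    thr = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    out = dataset.counts.copy().astype(float)
    rows = dataset.probe_class.isin([REFERENCE, TARGET])
    corrected = out.loc[rows].sub(thr, axis=1)
    out.loc[rows] = corrected.clip(lower=1.0)
    return dataset.with_counts(out)


def qc_positive_controls(dataset: NanoStringDataset) -> tuple[bool, float]:
    """Gate on the spread of per-sample positive-control means.

    Returns ``(pass, ratio)`` where ratio is max/min of the per-sample
    averages; the gate passes iff the ratio is below 3.  A zero mean
    yields an infinite ratio and a fail.
    """
    if dataset.counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    means = dataset.counts.loc[dataset.probes(POSITIVE)].mean(axis=0)
    lo, hi = float(means.min()), float(means.max())
    if lo == 0.0:
        return False, np.inf
    ratio = hi / lo
    return ratio < 3.0, ratio


def genorm_m_values(log2_counts: pd.DataFrame) -> pd.Series:
    """geNorm stability M per candidate (rows) over samples (columns).

    ``M_j`` is the mean over the other candidates of the (n-1) standard
    deviation across samples of ``log2(x_j / x_k)``.
    """
    genes = list(log2_counts.index)
    if len(genes) < 2:
        raise ValueError("need >= 2 candidates")
    arr = log2_counts.to_numpy(dtype=float)
    m = np.empty(len(genes))
    for j in range(len(genes)):
        diffs = arr[j][None, :] - np.delete(arr, j, axis=0)
        m[j] = np.mean(np.std(diffs, axis=1, ddof=1))
    return pd.Series(m, index=genes, name="M")


def genorm_select(dataset: NanoStringDataset, k: int = 12) -> GeNormResult:
    """Iteratively drop the least stable reference candidate until k remain.

    Candidates are the ``ref`` probes; counts must be strictly positive
    (run :func:`background_correct` first).  Ties in M are resolved by
    dropping the later-listed candidate, so identical samples keep the
    first k in input order.
    """
    cand = list(dataset.probes(REFERENCE))
    if len(cand) < 3:
        raise ValueError("need >= 3 reference candidates")
    counts = dataset.counts.loc[cand]
    if (counts.to_numpy() <= 0).any():
        raise ValueError("zero counts; background-correct first")
    if len(cand) <= k:
        if len(cand) < k:
            warnings.warn(
                f"only {len(cand)} candidates for k={k}; returning all",
                stacklevel=2,
            )
        m0 = genorm_m_values(np.log2(counts))
        return GeNormResult(m0, list(m0.sort_values(kind="stable").index),
                            cand, [])
    logs = np.log2(counts)
    m0 = genorm_m_values(logs)
    current = list(cand)
    dropped: list[str] = []
    while len(current) > max(k, 2):
        m = genorm_m_values(logs.loc[current])
        worst = m[::-1].idxmax()  # ties -> later-listed candidate
        current.remove(worst)
        dropped.append(worst)
    ranking = current + dropped[::-1]
    return GeNormResult(m0, ranking, current, dropped)


def normalize_counts(
    dataset: NanoStringDataset, reference_set
) -> NanoStringDataset:
    """Scale each sample by its reference-gene geometric mean.

    Per sample the factor is the geometric mean of the reference counts;
    non-negative-control probes are multiplied by
    ``global_reference_geomean / sample_factor`` so the reference
    geomeans are equal across samples afterwards, on a count-like scale.
    """
    refs = list(reference_set)
    ref_counts = dataset.counts.loc[refs]
    if (ref_counts.to_numpy() <= 0).any():
        raise ValueError("reference counts must be positive in every sample")
    factors = np.exp(np.log(ref_counts).mean(axis=0))
    anchor = float(np.exp(np.log(factors).mean()))
    out = dataset.counts.copy().astype(float)
    rows = dataset.probe_class != NEGATIVE
    out.loc[rows] = out.loc[rows].mul(anchor / factors, axis=1)
    return dataset.with_counts(out)


def _log_geomean(frame: pd.DataFrame, replicate: pd.Series | None) -> pd.Series:
    """Geometric mean over samples, averaging technical samples first."""
    logs = np.log2(frame)
    if replicate is not None:
        logs = logs.T.groupby(replicate.loc[frame.columns]).mean().T
    return logs.mean(axis=1)


def fold_changes(
    dataset: NanoStringDataset,
    treated: str = "GA",
    control: str = "DMSO",
    average_technical: bool = True,
) -> pd.Series:
    """Per-target log2 ratio of condition geometric means (treated/control).

    With ``average_technical`` and a replicate map on the dataset,
    technical samples of one biological replicate are first averaged on
    the log scale.
    """
    t_samples = dataset.samples(treated)
    c_samples = dataset.samples(control)
    if not t_samples or not c_samples:
        raise ValueError("need >= 1 sample per condition")
    targets = dataset.probes(TARGET)
    rep = dataset.replicate if average_technical else None
    t_gm = _log_geomean(dataset.counts.loc[targets, t_samples], rep)
    c_gm = _log_geomean(dataset.counts.loc[targets, c_samples], rep)
    fc = t_gm - c_gm
    fc.name = "log2_fc"
    return fc


def read_counts_csv(counts_path, samples_path) -> NanoStringDataset:
    """Read a probe-by-sample counts CSV plus a sample sheet.

    The counts file has a ``probe`` column, a ``class`` column
    (neg/pos/ref/target) and one column per sample.  The sample sheet
    maps ``sample`` to ``condition`` (and optionally ``replicate``).
    """
    raw = pd.read_csv(counts_path)
    raw = raw.set_index("probe")
    probe_class = raw.pop("class")
    sheet = pd.read_csv(samples_path).set_index("sample")
    replicate = sheet["replicate"] if "replicate" in sheet.columns else None
    return NanoStringDataset(
        raw.astype(float), probe_class, sheet["condition"], replicate
    )
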