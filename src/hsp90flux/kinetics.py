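"""First-order pulse-chase turnover model: decay/synthesis fits, half-lives.

Model per protein per condition: the pre-existing ("chase") pool decays as
``H(t) = H0 * exp(-k_d t)`` and the newly synthesized ("pulse") pool
accumulates as ``N(t) = (V_s / k_d) * (1 - exp(-k_d t))``.  ``k_d`` is
fitted by log-linear least squares on the chase signal; ``V_s`` by linear
least squares on the pulse signal conditional on the fitted ``k_d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PulseChaseSeries",
    "KineticFit",
    "CategorySummary",
    "fit_decay",
    "fit_synthesis",
    "half_life",
    "fit_series_pair",
    "fit_all",
    "adjust_by_global_median",
    "add_adjusted_columns",
    "summarize_category",
    "read_series_csv",
    "write_series_csv",
]

CONTROL = "control"
TREATED = "treated"


@dataclass
class PulseChaseSeries:
    """Old-pool ("chase") and new-pool ("pulse") signals for one protein."""

    protein_id: str
    condition: str
    times_h: np.ndarray
    old_signal: np.ndarray
    new_signal: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.old_signal = np.asarray(self.old_signal, dtype=float)
        self.new_signal = np.asarray(self.new_signal, dtype=float)
        if not (len(self.times_h) == len(self.old_signal) == len(self.new_signal)):
            raise ValueError("times and signals must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be sorted ascending")
        if self.condition not in (CONTROL, TREATED):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class KineticFit:
    """Per-protein rates and half-lives in both conditions, plus ratios."""

    protein_id: str
    kd_ctrl: float
    kd_treated: float
    vs_ctrl: float
    vs_treated: float

    @property
    def thalf_ctrl(self) -> float:
        return half_life(self.kd_ctrl)

    @property
    def thalf_treated(self) -> float:
        return half_life(self.kd_treated)

    @property
    def kd_ratio(self) -> float:
        # inf when the control pool did not measurably decay; nan when neither did
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(np.float64(self.kd_treated) / np.float64(self.kd_ctrl))

    @property
    def vs_ratio(self) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(np.float64(self.vs_treated) / np.float64(self.vs_ctrl))

    @property
    def thalf_ratio(self) -> float:
        # reciprocal of the decay-rate ratio by construction
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(np.float64(self.kd_ctrl) / np.float64(self.kd_treated))


@dataclass
class CategorySummary:
    """Mean adjusted log2 ratios and raw mean half-lives for one category."""

    category: str
    n: int
    mean_adj_log2_vs_ratio: float
    mean_adj_log2_kd_ratio: float
    mean_adj_log2_thalf_ratio: float
    mean_thalf_ctrl_h: float
    mean_thalf_treated_h: float
    mean_adj_log2_abundance_ratio: float = field(default=np.nan)


def fit_decay(series: PulseChaseSeries) -> float | None:
    """Decay rate constant from the chase signal, 1/h.

    Ordinary least squares of ``ln(old_signal)`` against time; ``k_d`` is
    minus the slope, clamped at 0.  Returns None with fewer than two
    positive chase points.
    """
    ok = np.isfinite(series.old_signal) & (series.old_signal > 0)
    if ok.sum() < 2:
        return None
    t = series.times_h[ok]
    y = np.log(series.old_signal[ok])
    slope = np.polyfit(t, y, 1)[0]
    return max(-float(slope), 0.0)


def fit_synthesis(series: PulseChaseSeries, k_d: float) -> float | None:
    """Synthesis rate from the pulse signal given a fitted ``k_d``.

    The model ``N(t) = V_s * g(t)`` with ``g(t) = (1 - exp(-k_d t))/k_d``
    (``g(t) = t`` in the ``k_d = 0`` limit) is linear in ``V_s``; the
    least-squares solution is closed form.  Returns None when no
    post-zero time point is available.
    """
    if k_d < 0:
        raise ValueError("k_d must be non-negative")
    ok = np.isfinite(series.new_signal) & (series.times_h > 0)
    if not ok.any():
        return None
    t = series.times_h[ok]
    n = series.new_signal[ok]
    if k_d > 0:
        g = (1.0 - np.exp(-k_d * t)) / k_d
    else:
        g = t
    return float((n * g).sum() / (g * g).sum())


def half_life(k_d: float) -> float:
    """``ln 2 / k_d`` in hours; infinite at ``k_d = 0``."""
    if k_d < 0:
        raise ValueError("negative decay rate")
    if k_d == 0:
        return np.inf
    return float(np.log(2.0) / k_d)


def fit_series_pair(
    ctrl: PulseChaseSeries, treated: PulseChaseSeries
) -> KineticFit | None:
    """Fit both conditions for one protein; None when either fit fails."""
    if ctrl.protein_id != treated.protein_id:
        raise ValueError("series pair must share a protein id")
    kd_c = fit_decay(ctrl)
    kd_t = fit_decay(treated)
    if kd_c is None or kd_t is None:
        return None
    vs_c = fit_synthesis(ctrl, kd_c)
    vs_t = fit_synthesis(treated, kd_t)
    if vs_c is None or vs_t is None:
        return None
    return KineticFit(ctrl.protein_id, kd_c, kd_t, vs_c, vs_t)


def fit_all(series: list[PulseChaseSeries]) -> pd.DataFrame:
    """Fit every protein with a complete control/treated series pair.

    Returns a data frame indexed by protein id with rates, half-lives and
    log2 condition ratios (treated over control).
    """
    by_protein: dict[str, dict[str, PulseChaseSeries]] = {}
    for s in series:
        by_protein.setdefault(s.protein_id, {})[s.condition] = s
    rows = []
    for pid, pair in by_protein.items():
        if CONTROL not in pair or TREATED not in pair:
            continue
        fit = fit_series_pair(pair[CONTROL], pair[TREATED])
        if fit is None:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rows.append(
                {
                    "protein_id": pid,
                    "kd_ctrl": fit.kd_ctrl,
                    "kd_treated": fit.kd_treated,
                    "vs_ctrl": fit.vs_ctrl,
                    "vs_treated": fit.vs_treated,
                    "thalf_ctrl": fit.thalf_ctrl,
                    "thalf_treated": fit.thalf_treated,
                    "log2_kd_ratio": float(np.log2(fit.kd_ratio)),
                    "log2_vs_ratio": float(np.log2(fit.vs_ratio)),
                    "log2_thalf_ratio": float(np.log2(fit.thalf_ratio)),
                }
            )
    return pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame(
        columns=[
            "kd_ctrl", "kd_treated", "vs_ctrl", "vs_treated",
            "thalf_ctrl", "thalf_treated",
            "log2_kd_ratio", "log2_vs_ratio", "log2_thalf_ratio",
        ]
    )


def adjust_by_global_median(values) -> np.ndarray:
    """Subtract the median of all finite values from each value.

    Centers the dataset so its median is 0; non-finite entries pass
    through unchanged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("need at least one finite value")
    med = np.median(x[finite])
    out = x.copy()
    out[finite] = x[finite] - med
    return out


def add_adjusted_columns(fits: pd.DataFrame) -> pd.DataFrame:
    """Append global-median-adjusted log2 ratio columns to a fit table."""
    out = fits.copy()
    for col in ("log2_kd_ratio", "log2_vs_ratio", "log2_thalf_ratio"):
        out[f"adj_{col}"] = adjust_by_global_median(out[col].to_numpy())
    return out


def summarize_category(
    fits: pd.DataFrame, category_membership: dict
) -> list[CategorySummary]:
    """Arithmetic category means of adjusted ratios and raw half-lives.

    ``category_membership`` maps category name -> iterable of protein
    ids.  ``fits`` must carry the ``adj_*`` columns (see
    :func:`add_adjusted_columns`).  Empty categories are omitted.
    """
    summaries = []
    for name, members in category_membership.items():
        sub = fits.loc[fits.index.intersection(list(members))]
        if sub.empty:
            continue
        summaries.append(
            CategorySummary(
                category=name,
                n=len(sub),
                mean_adj_log2_vs_ratio=float(sub["adj_log2_vs_ratio"].mean()),
                mean_adj_log2_kd_ratio=float(sub["adj_log2_kd_ratio"].mean()),
                mean_adj_log2_thalf_ratio=float(sub["adj_log2_thalf_ratio"].mean()),
                mean_thalf_ctrl_h=float(sub["thalf_ctrl"].mean()),
                mean_thalf_treated_h=float(sub["thalf_treated"].mean()),
            )
        )
    return summaries


def read_series_csv(path) -> list[PulseChaseSeries]:
    """Read long-format series (protein, condition, time_h, old, new)."""
    df = pd.read_csv(path)
    series = []
    for (pid, cond), grp in df.groupby(["protein_id", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        series.append(
            PulseChaseSeries(
                str(pid),
                str(cond),
                grp["time_h"].to_numpy(),
                grp["old_signal"].to_numpy(),
                grp["new_signal"].to_numpy(),
            )
        )
    return series


def write_series_csv(series: list[PulseChaseSeries], path) -> None:
    rows = [
        {
            "protein_id": s.protein_id,
            "condition": s.condition,
            "time_h": t,
            "old_signal": o,
            "new_signal": n,
        }
        for s in series
        for t, o, n in zip(s.times_h, s.old_signal, s.new_signal)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
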