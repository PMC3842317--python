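"""Synthetic SILAC tables, pulse-chase time courses and nCounter matrices.

Every generator takes a frozen config with a seed and returns both the
dataset and its ground truth, so each downstream stage can be tested for
exact recovery without any external data.  Lognormal variation is used
throughout: ratios and counts are positive and multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import CHANGE_TEMPLATES, CLUSTER_NO_CHANGE
from .kinetics import CONTROL, TREATED, PulseChaseSeries
from .nanostring import NanoStringDataset
from .silac import ProteinGroupTable

__all__ = [
    "SilacSimConfig",
    "PcSilacPreset",
    "NanoSimConfig",
    "default_category_overrides",
    "generate_stsilac_table",
    "generate_pcsilac_series",
    "generate_nanostring_counts",
]

LN2 = float(np.log(2.0))


def _lognormal(rng: np.random.Generator, median: float, logsd: float, size) :
    """Lognormal draw parameterized by its median and log-space sd."""
    return median * np.exp(rng.normal(0.0, logsd, size=size)) if logsd > 0 \
        else np.full(size, float(median))


def _cv_to_logsd(cv: float) -> float:
    # CV of exp(N(0, s)) is sqrt(e^{s^2} - 1)
    return float(np.sqrt(np.log1p(cv * cv)))


# ---------------------------------------------------------------------------
# stSILAC table generator


@dataclass(frozen=True)
class SilacSimConfig:
    """Configuration for the synthetic stSILAC protein-group table."""

    n_proteins: int = 100
    replicates: int = 3
    swapped_replicates: frozenset = frozenset({3})
    timepoints_h: tuple[int, ...] = (6, 20)
    cluster_mix: dict = field(default_factory=dict)  # pattern label -> fraction
    effect_size_log2: float = 0.5
    noise_sd_log2: float = 0.15
    contaminant_fraction: float = 0.0
    reverse_fraction: float = 0.0
    single_evidence_fraction: float = 0.0
    outlier_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.effect_size_log2 <= 0 or self.noise_sd_log2 < 0:
            raise ValueError("effect size must be > 0 and noise sd >= 0")
        fracs = (
            self.contaminant_fraction,
            self.reverse_fraction,
            self.single_evidence_fraction,
            self.outlier_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        for label, frac in self.cluster_mix.items():
            if not 1 <= int(label) <= len(CHANGE_TEMPLATES):
                raise ValueError(f"unknown pattern label {label}")
            if not 0 <= frac <= 1:
                raise ValueError("cluster_mix fractions must lie in [0, 1]")
        if sum(self.cluster_mix.values()) > 1 + 1e-12:
            raise ValueError("cluster_mix fractions must sum to <= 1")


def generate_stsilac_table(
    cfg: SilacSimConfig,
) -> tuple[ProteinGroupTable, pd.DataFrame]:
    """Generate a protein-group table with planted temporal patterns.

    Returns the table (as written to disk: swapped replicates carry
    inverted H/L ratios) and a ground-truth frame indexed by protein id
    with the planted ``pattern`` label (13 = invariant), ``outlier`` and
    ``single_evidence`` flags.  Contaminant and reverse rows are planted
    on top of ``n_proteins`` and carry pattern 0 in the truth frame.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tps = tuple(cfg.timepoints_h)
    reps = tuple(range(1, cfg.replicates + 1))

    # deterministic allocation of pattern labels
    labels: list[int] = []
    for label, frac in sorted(cfg.cluster_mix.items()):
        labels.extend([int(label)] * int(round(frac * cfg.n_proteins)))
    labels = labels[: cfg.n_proteins]
    labels.extend([CLUSTER_NO_CHANGE] * (cfg.n_proteins - len(labels)))

    n_out = int(round(cfg.outlier_fraction * cfg.n_proteins))
    outlier_rows = set(rng.choice(cfg.n_proteins, size=n_out, replace=False))
    n_single = int(round(cfg.single_evidence_fraction * cfg.n_proteins))
    single_rows = set(
        rng.choice(
            sorted(set(range(cfg.n_proteins)) - outlier_rows),
            size=min(n_single, cfg.n_proteins - n_out),
            replace=False,
        )
    )

    rows, truth = [], []
    for i in range(cfg.n_proteins):
        pid = f"P{i + 1:05d}"
        label = labels[i]
        template = (
            (0, 0, 0) if label == CLUSTER_NO_CHANGE else CHANGE_TEMPLATES[label - 1]
        )
        row: dict = {
            "group_ids": pid,
            "gene_name": f"GENE{i + 1}",
            "contaminant": "-",
            "reverse": "-",
        }
        for ti, t in enumerate(tps):
            mu = template[ti + 1] * cfg.effect_size_log2
            for r in reps:
                x = mu + rng.normal(0.0, cfg.noise_sd_log2)
                ratio = 2.0**x
                if r in cfg.swapped_replicates:
                    ratio = 1.0 / ratio  # emitted with inverted labels
                row[f"ratio_r{r}_t{t}"] = ratio
                row[f"evidence_r{r}_t{t}"] = int(rng.integers(2, 9))
        if i in outlier_rows:
            # violate the x1.41 replicate-agreement rule at one time point
            t = tps[int(rng.integers(len(tps)))]
            r = reps[int(rng.integers(len(reps)))]
            row[f"ratio_r{r}_t{t}"] *= 1.6
        if i in single_rows:
            t = tps[int(rng.integers(len(tps)))]
            r = reps[int(rng.integers(len(reps)))]
            row[f"evidence_r{r}_t{t}"] = 1
        rows.append(row)
        truth.append(
            {
                "protein_id": pid,
                "pattern": label,
                "outlier": i in outlier_rows,
                "single_evidence": i in single_rows,
            }
        )

    def _junk_row(pid: str, kind: str) -> dict:
        row = {
            "group_ids": pid,
            "gene_name": pid,
            "contaminant": "+" if kind == "contaminant" else "-",
            "reverse": "+" if kind == "reverse" else "-",
        }
        for t in tps:
            for r in reps:
                row[f"ratio_r{r}_t{t}"] = float(
                    2.0 ** rng.normal(0.0, max(cfg.noise_sd_log2, 0.1))
                )
                row[f"evidence_r{r}_t{t}"] = int(rng.integers(2, 9))
        return row

    n_cont = int(round(cfg.contaminant_fraction * cfg.n_proteins))
    n_rev = int(round(cfg.reverse_fraction * cfg.n_proteins))
    for j in range(n_cont):
        pid = f"CON{j + 1:04d}"
        rows.append(_junk_row(pid, "contaminant"))
        truth.append({"protein_id": pid, "pattern": 0, "outlier": False,
                      "single_evidence": False})
    for j in range(n_rev):
        pid = f"REV{j + 1:04d}"
        rows.append(_junk_row(pid, "reverse"))
        truth.append({"protein_id": pid, "pattern": 0, "outlier": False,
                      "single_evidence": False})

    df = pd.DataFrame(rows)
    df["is_contaminant"] = df.pop("contaminant") == "+"
    df["is_reverse"] = df.pop("reverse") == "+"
    table = ProteinGroupTable(df, reps, tps)
    truth_df = pd.DataFrame(truth).set_index("protein_id")
    return table, truth_df


# ---------------------------------------------------------------------------
# pulse-chase generator


def default_category_overrides() -> dict:
    """Built-in category presets with distinct control/treated half-lives."""
    return {
        "hsp90_cofactors": {
            "ctrl_halflife_mean_h": 321.0,
            "treated_halflife_mean_h": 43.5,
            "n": 40,
        },
        "kinases": {
            "ctrl_halflife_mean_h": 39.9,
            "treated_halflife_mean_h": 22.5,
            "n": 32,
        },
    }


@dataclass(frozen=True)
class PcSilacPreset:
    """Preset for the treated-vs-control pulse-chase generator.

    Defaults emulate a global slowdown of synthesis (median factor 0.57)
    and acceleration of decay (median factor 1.73) against a control
    half-life distribution with median 55.9 h.
    """

    n_proteins: int = 911
    ctrl_halflife_median_h: float = 55.9
    ctrl_halflife_logsd: float = 0.8
    kd_factor_median: float = 1.73
    kd_factor_logsd: float = 0.35
    vs_ctrl_median: float = 10.0
    vs_ctrl_logsd: float = 0.8
    vs_factor_median: float = 0.57
    vs_factor_logsd: float = 0.35
    sample_times_h: tuple[float, ...] = (0.0, 6.0, 20.0)
    # with only 3 sampled times the arithmetic mean of ln2/k_d is extremely
    # heavy-tailed for slow-decaying categories; 2% channel noise keeps
    # category mean half-lives estimable on this grid
    noise_cv: float = 0.02
    category_overrides: dict = field(default_factory=default_category_overrides)
    category_halflife_logsd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        positives = (
            self.ctrl_halflife_median_h,
            self.kd_factor_median,
            self.vs_ctrl_median,
            self.vs_factor_median,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("medians must be positive")
        times = tuple(self.sample_times_h)
        if times[0] != 0 or any(np.diff(times) <= 0):
            raise ValueError("sample_times_h must be sorted and start at 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")
        n_over = sum(o["n"] for o in self.category_overrides.values())
        if n_over > self.n_proteins:
            raise ValueError("category overrides exceed n_proteins")
        for name, o in self.category_overrides.items():
            if o["ctrl_halflife_mean_h"] <= 0 or o["treated_halflife_mean_h"] <= 0:
                raise ValueError(f"category {name}: half-life means must be > 0")


def _mean_lognormal(rng, mean: float, logsd: float, size) -> np.ndarray:
    """Lognormal with the requested arithmetic mean."""
    mu = np.log(mean) - 0.5 * logsd * logsd
    return np.exp(rng.normal(mu, logsd, size=size))


def generate_pcsilac_series(
    preset: PcSilacPreset,
) -> tuple[list[PulseChaseSeries], pd.DataFrame]:
    """Generate control/treated pulse-chase series with known rates.

    Per protein, the control decay constant derives from a lognormal
    half-life; the treated constant multiplies it by a lognormal factor
    (ditto for the synthesis rates).  Old pools start at the control
    steady state ``V_s,ctrl / k_d,ctrl`` and decay exponentially; new
    pools rise to the condition steady state.  Both signals carry
    multiplicative lognormal noise of the configured CV at every sampled
    time (the new pool is exactly 0 at t=0).

    Category-override proteins draw per-condition half-lives around the
    stated category means instead of using the global factor model.

    Returns the series list (two per protein) and a truth frame indexed
    by protein id with ``category``, true ``kd_ctrl``, ``kd_treated``,
    ``vs_ctrl``, ``vs_treated``.
    """
    preset.validate()
    rng = np.random.default_rng(preset.seed)
    times = np.asarray(preset.sample_times_h, dtype=float)
    noise_sd = _cv_to_logsd(preset.noise_cv)

    n_over = sum(o["n"] for o in preset.category_overrides.values())
    n_base = preset.n_proteins - n_over

    categories: list[str] = ["" ] * 0
    kd_c = np.empty(preset.n_proteins)
    kd_t = np.empty(preset.n_proteins)

    thalf_c = _lognormal(
        rng, preset.ctrl_halflife_median_h, preset.ctrl_halflife_logsd, n_base
    )
    kd_c[:n_base] = LN2 / thalf_c
    kd_t[:n_base] = kd_c[:n_base] * _lognormal(
        rng, preset.kd_factor_median, preset.kd_factor_logsd, n_base
    )
    categories.extend([""] * n_base)

    pos = n_base
    for name, o in preset.category_overrides.items():
        n = int(o["n"])
        tc = _mean_lognormal(
            rng, o["ctrl_halflife_mean_h"], preset.category_halflife_logsd, n
        )
        tt = _mean_lognormal(
            rng, o["treated_halflife_mean_h"], preset.category_halflife_logsd, n
        )
        kd_c[pos : pos + n] = LN2 / tc
        kd_t[pos : pos + n] = LN2 / tt
        categories.extend([name] * n)
        pos += n

    vs_c = _lognormal(
        rng, preset.vs_ctrl_median, preset.vs_ctrl_logsd, preset.n_proteins
    )
    vs_t = vs_c * _lognormal(
        rng, preset.vs_factor_median, preset.vs_factor_logsd, preset.n_proteins
    )

    series: list[PulseChaseSeries] = []
    truth_rows = []
    for i in range(preset.n_proteins):
        pid = f"P{i + 1:05d}"
        h0 = vs_c[i] / kd_c[i]  # proteostatic steady state before treatment
        for cond, kd, vs in (
            (CONTROL, kd_c[i], vs_c[i]),
            (TREATED, kd_t[i], vs_t[i]),
        ):
            old = h0 * np.exp(-kd * times)
            new = (vs / kd) * (1.0 - np.exp(-kd * times))
            if noise_sd > 0:
                old = old * np.exp(rng.normal(0.0, noise_sd, size=times.size))
                fuzz = np.exp(rng.normal(0.0, noise_sd, size=times.size))
                fuzz[times == 0] = 1.0  # new pool is exactly empty at t=0
                new = new * fuzz
            series.append(PulseChaseSeries(pid, cond, times, old, new))
        truth_rows.append(
            {
                "protein_id": pid,
                "category": categories[i],
                "kd_ctrl": kd_c[i],
                "kd_treated": kd_t[i],
                "vs_ctrl": vs_c[i],
                "vs_treated": vs_t[i],
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return series, truth


# ---------------------------------------------------------------------------
# nCounter generator


@dataclass(frozen=True)
class NanoSimConfig:
    """Configuration for the synthetic nCounter count matrix.

    Counts are ``signal + background``: negative controls carry the
    background alone, so at zero noise the background-correction step
    recovers every planted signal exactly.
    """

    n_targets: int = 88
    n_reference: int = 12
    n_negative: int = 6
    n_positive: int = 6
    samples_per_condition: int = 2
    fold_change_map: dict = field(default_factory=dict)  # gene -> true log2 FC
    count_noise_logsd: float = 0.1
    baseline_count_range: tuple[int, int] = (50, 5000)
    background_level: float = 10.0
    qc_failure: bool = False
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_targets, self.n_reference, self.n_negative,
                  self.n_positive, self.samples_per_condition)
        if any(c < 1 for c in counts):
            raise ValueError("counts must be >= 1")
        lo, hi = self.baseline_count_range
        if not (0 < lo < hi):
            raise ValueError("baseline range must satisfy 0 < low < high")
        if self.count_noise_logsd < 0 or self.background_level < 0:
            raise ValueError("noise and background must be >= 0")


# positive-control ladder, count-like scale
_POS_LADDER = (8000.0, 2000.0, 500.0, 125.0, 32.0, 8.0)


def generate_nanostring_counts(
    cfg: NanoSimConfig,
) -> tuple[NanoStringDataset, pd.Series]:
    """Generate an nCounter dataset with planted log2 fold-changes.

    Targets not named in ``fold_change_map`` have a true fold-change of
    0.  With ``qc_failure`` one treated sample's positive controls are
    inflated past the 3x gate.  Returns the dataset and the full truth
    map (per target gene).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.samples_per_condition
    samples = [f"DMSO_{i + 1}" for i in range(m)] + [
        f"GA_{i + 1}" for i in range(m)
    ]
    condition = pd.Series(
        ["DMSO"] * m + ["GA"] * m, index=samples, name="condition"
    )
    replicate = pd.Series(
        [f"rep{i // 2 + 1}" for i in range(m)] * 2, index=samples,
        name="replicate",
    )

    def noise(size):
        # count_noise_logsd is the sd of log2 counts
        if cfg.count_noise_logsd == 0:
            return np.ones(size)
        return 2.0 ** rng.normal(0.0, cfg.count_noise_logsd, size=size)

    lo, hi = cfg.baseline_count_range
    probes, classes, rows = [], [], []

    for j in range(cfg.n_negative):
        probes.append(f"NEG_{j + 1}")
        classes.append("neg")
        rows.append(cfg.background_level * noise(len(samples)))

    for j in range(cfg.n_positive):
        probes.append(f"POS_{j + 1}")
        classes.append("pos")
        level = _POS_LADDER[j % len(_POS_LADDER)]
        rows.append(level * noise(len(samples)) + cfg.background_level)

    for j in range(cfg.n_reference):
        probes.append(f"REF_{j + 1}")
        classes.append("ref")
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rows.append(base * noise(len(samples)) + cfg.background_level)

    truth = {}
    for j in range(cfg.n_targets):
        gene = f"TGT_{j + 1}"
        probes.append(gene)
        classes.append("target")
        fc = float(cfg.fold_change_map.get(gene, 0.0))
        truth[gene] = fc
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        signal = np.array(
            [base if condition[s] == "DMSO" else base * 2.0**fc for s in samples]
        )
        rows.append(signal * noise(len(samples)) + cfg.background_level)

    counts = pd.DataFrame(rows, index=probes, columns=samples, dtype=float)
    if cfg.qc_failure:
        pos_rows = [p for p, c in zip(probes, classes) if c == "pos"]
        counts.loc[pos_rows, samples[-1]] *= 4.0  # planted QC breach
    dataset = NanoStringDataset(
        counts,
        pd.Series(classes, index=probes, name="class"),
        condition,
        replicate,
    )
    return dataset, pd.Series(truth, name="true_log2_fc")
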