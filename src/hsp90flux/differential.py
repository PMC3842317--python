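"""Significance calling and model-correlation temporal clustering.

Per time point, log2 ratios across replicates are tested against zero with
a one-sample t-test and corrected with Benjamini-Hochberg.  Proteins
significant at one or more time points are assigned to the qualitative
temporal template (over the trajectory 0 -> 6h -> 20h, with an appended
zero reference point) maximizing Pearson correlation.  Non-significant
proteins go to cluster 13; proteins detected at a single time point go to
cluster 14.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .silac import ProteinGroupTable, median_log2

__all__ = [
    "CHANGE_TEMPLATES",
    "NO_CHANGE_TEMPLATE",
    "ALL_TEMPLATES",
    "CLUSTER_NO_CHANGE",
    "CLUSTER_ONE_TIMEPOINT",
    "ClusterAssignment",
    "one_sample_ttest",
    "bh_adjust",
    "assign_cluster",
    "cluster_proteins",
    "enrichment_hypergeometric",
]

# 12 qualitative change templates over (ref, 6h, 20h), in canonical order;
# the 1-based position is the cluster id.
CHANGE_TEMPLATES: tuple[tuple[int, int, int], ...] = (
    (0, 2, 1),
    (0, 1, 2),
    (0, 1, 1),
    (0, 1, 0),
    (0, 1, -1),
    (0, 0, 1),
    (0, 0, -1),
    (0, -1, 1),
    (0, -1, 0),
    (0, -1, -1),
    (0, -1, -2),
    (0, -2, -1),
)
NO_CHANGE_TEMPLATE: tuple[int, int, int] = (0, 0, 0)
#: All qualitative patterns, change templates plus the no-change pattern.
ALL_TEMPLATES: tuple[tuple[int, int, int], ...] = CHANGE_TEMPLATES + (
    NO_CHANGE_TEMPLATE,
)

CLUSTER_NO_CHANGE = 13
CLUSTER_ONE_TIMEPOINT = 14


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label 1..14 and, for template clusters, the best correlation."""

    protein_id: str
    cluster: int
    best_correlation: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.cluster <= 14:
            raise ValueError(f"cluster out of range: {self.cluster}")
        if self.cluster <= 12 and self.best_correlation is None:
            raise ValueError("template clusters require a correlation")


def one_sample_ttest(values) -> tuple[float, int, float]:
    """One-sample two-sided t-test of mean zero.

    Returns ``(t, df, p)`` with ``t = mean / (sd / sqrt(n))`` using the
    n-1 sample standard deviation and ``df = n - 1``.  Degenerate zero-sd
    samples return ``p = 1`` when the mean is zero and ``p = 0`` otherwise
    (with ``t`` of 0 or signed infinity).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean) * np.inf), df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone, capped at 1, returned in the input order.  NaNs propagate
    and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0.0:
        return np.nan
    return float((a * b).sum() / denom)


def assign_cluster(
    trajectory,
    significant: bool,
    detected_timepoints: int = 2,
    protein_id: str = "",
) -> ClusterAssignment:
    """Assign a (0, m6, m20) trajectory to a temporal cluster.

    Parameters
    ----------
    trajectory : sequence of 3 floats
        Median log2 ratios prefixed with the zero reference point.
    significant : bool
        Whether any time point passed the (adjusted) significance cut.
    detected_timepoints : int
        Number of time points with data; fewer than 2 yields cluster 14.
    """
    if detected_timepoints < 2:
        return ClusterAssignment(protein_id, CLUSTER_ONE_TIMEPOINT)
    if not significant:
        return ClusterAssignment(protein_id, CLUSTER_NO_CHANGE)
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape != (3,):
        raise ValueError("trajectory must have 3 points (0, m6, m20)")
    if traj[0] != 0.0:
        raise ValueError("trajectory must begin with the 0 reference")
    if np.allclose(traj, traj[0]):
        warnings.warn(
            f"zero-variance trajectory for significant protein {protein_id!r};"
            " falling back to cluster 13",
            stacklevel=2,
        )
        return ClusterAssignment(protein_id, CLUSTER_NO_CHANGE)
    corrs = np.array(
        [_pearson(traj, np.asarray(tpl, dtype=float)) for tpl in CHANGE_TEMPLATES]
    )
    # ties (within 1e-9) resolved by canonical template order
    best = int(np.argmax(np.where(np.isnan(corrs), -np.inf, corrs)))
    for i, c in enumerate(corrs):
        if not np.isnan(c) and c > corrs[best] - 1e-9:
            best = i
            break
    return ClusterAssignment(protein_id, best + 1, float(corrs[best]))


def cluster_proteins(
    table: ProteinGroupTable,
    alpha: float = 0.05,
    pooled_bh: bool = False,
) -> pd.DataFrame:
    """Run per-time-point tests, BH correction and cluster assignment.

    Returns a data frame indexed like ``table.df`` with, per time point
    ``t``: ``median_log2_t{t}``, ``mean_log2_t{t}``, ``t_t{t}``,
    ``df_t{t}``, ``p_t{t}``, ``q_t{t}``; plus ``significant_any``,
    ``cluster`` and ``best_correlation``.

    BH correction is applied per time point by default; ``pooled_bh``
    pools raw p-values across both time points instead.
    """
    tps = table.timepoints
    out = pd.DataFrame(index=table.df.index)
    out["group_ids"] = table.df["group_ids"]
    out["gene_name"] = table.df["gene_name"]
    for t in tps:
        block = table.ratios(t).to_numpy(dtype=float)
        logs = np.full_like(block, np.nan)
        ok = np.isfinite(block)
        logs[ok] = np.log2(block[ok])
        n = ok.sum(axis=1)
        med = median_log2(table, t)
        means = np.full(len(block), np.nan)
        tstat = np.full(len(block), np.nan)
        dfree = np.full(len(block), np.nan)
        pval = np.full(len(block), np.nan)
        for i in range(len(block)):
            if n[i] >= 2:
                ti, dfi, pi = one_sample_ttest(logs[i][ok[i]])
                tstat[i], dfree[i], pval[i] = ti, dfi, pi
                means[i] = logs[i][ok[i]].mean()
            elif n[i] == 1:
                means[i] = logs[i][ok[i]][0]
        out[f"median_log2_t{t}"] = med
        out[f"mean_log2_t{t}"] = means
        out[f"t_t{t}"] = tstat
        out[f"df_t{t}"] = dfree
        out[f"p_t{t}"] = pval
    if pooled_bh:
        pooled = np.concatenate([out[f"p_t{t}"].to_numpy() for t in tps])
        adj = bh_adjust(pooled)
        for i, t in enumerate(tps):
            out[f"q_t{t}"] = adj[i * len(out) : (i + 1) * len(out)]
    else:
        for t in tps:
            out[f"q_t{t}"] = bh_adjust(out[f"p_t{t}"].to_numpy())

    qcols = [f"q_t{t}" for t in tps]
    out["significant_any"] = (out[qcols] < alpha).any(axis=1)
    pcols = [f"p_t{t}" for t in tps]
    out["raw_significant_any"] = (out[pcols] < alpha).any(axis=1)

    clusters = np.empty(len(out), dtype=int)
    best = np.full(len(out), np.nan)
    detected = out[[f"median_log2_t{t}" for t in tps]].notna().sum(axis=1)
    for i, (idx, row) in enumerate(out.iterrows()):
        traj = (0.0,) + tuple(
            row[f"median_log2_t{t}"] if np.isfinite(row[f"median_log2_t{t}"]) else 0.0
            for t in tps
        )
        asg = assign_cluster(
            traj,
            bool(row["significant_any"]),
            int(detected.loc[idx]),
            protein_id=str(row["group_ids"]),
        )
        clusters[i] = asg.cluster
        if asg.best_correlation is not None:
            best[i] = asg.best_correlation
    out["cluster"] = clusters
    out["best_correlation"] = best
    return out


def enrichment_hypergeometric(
    query_genes, term_map: dict, background_genes
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of a query gene set.

    ``term_map`` maps term -> iterable of genes.  For each term with K
    hits in the background of size N and k hits in the query of size n:
    enrichment ``(k/n)/(K/N)`` and upper-tail ``p = P(X >= k)``; ``q`` is
    BH across the tested terms.  Terms with no background hits are
    skipped with a warning.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n, N = len(query), len(background)
    rows = []
    for term, genes in term_map.items():
        gset = set(genes) & background
        K = len(gset)
        if K == 0:
            warnings.warn(f"term {term!r} absent from background; skipped",
                          stacklevel=2)
            continue
        k = len(gset & query)
        enr = (k / n) / (K / N) if n else np.nan
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, enr, min(p, 1.0)))
    res = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "enrichment", "p"]
    )
    res["q"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    return res
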