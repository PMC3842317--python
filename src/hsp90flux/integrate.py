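"""Dataset alignment, network node-attribute export, pipeline orchestration.

Tables from the different assays are aligned on protein-group identity:
two rows match only when their accession sets are identical
(order-insensitive).  The pipeline runner wires the simulators through
filtering, testing/clustering, kinetics and nCounter processing and
writes every table plus a JSON run log.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, differential, kinetics, nanostring, silac, simulate

__all__ = [
    "align_datasets",
    "export_node_attributes",
    "run_pipeline",
]


def _id_set_key(series: pd.Series) -> pd.Series:
    return series.map(lambda s: frozenset(str(s).split(";")))


def align_datasets(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Outer-join two tables on identical protein-group id sets.

    Both tables must carry a ``group_ids`` column (semicolon-joined).
    Rows match iff their id sets are equal as sets; unmatched rows are
    retained with absent fields.  Duplicate id sets within one table are
    an error.
    """
    frames = []
    for tbl, suffix in zip((table_a, table_b), suffixes):
        if "group_ids" not in tbl.columns:
            raise ValueError("tables must have a group_ids column")
        key = _id_set_key(tbl["group_ids"])
        if key.duplicated().any():
            dup = tbl["group_ids"][key.duplicated()].iloc[0]
            raise ValueError(f"duplicate group id set within a table: {dup}")
        f = tbl.copy()
        f.index = key
        f.index.name = "_idset"
        frames.append(f.add_suffix(suffix))
    joint = frames[0].join(frames[1], how="outer")
    ga, gb = f"group_ids{suffixes[0]}", f"group_ids{suffixes[1]}"
    joint.insert(0, "group_ids", joint[ga].fillna(joint[gb]))
    joint = joint.drop(columns=[ga, gb]).reset_index(drop=True)
    return joint


def export_node_attributes(
    tested: pd.DataFrame,
    timepoints=(6, 20),
    alpha: float = 0.05,
    clamp_log2: float = 2.0,
) -> pd.DataFrame:
    """Node table for network tools: raw-p selection plus a color scale.

    Keeps rows with an uncorrected p below ``alpha`` at one or more time
    points.  Each log2 ratio gets a companion ``color_t{t}`` column
    linearly clamped to [-1, 1] at ``±clamp_log2`` log2 units (the
    red-to-blue thermogram midpoint 0 maps to 0).
    """
    pcols = [f"p_t{t}" for t in timepoints]
    keep = (tested[pcols] < alpha).any(axis=1)
    cols = ["group_ids", "gene_name"]
    out = tested.loc[keep, cols].copy()
    for t in timepoints:
        ratio = tested.loc[keep, f"median_log2_t{t}"]
        out[f"log2_t{t}"] = ratio
        out[f"p_t{t}"] = tested.loc[keep, f"p_t{t}"]
        out[f"color_t{t}"] = np.clip(ratio / clamp_log2, -1.0, 1.0)
    return out


_REQUIRED_STAGES = ("stsilac", "pcsilac", "nanostring")


def run_pipeline(config: dict, outdir) -> dict:
    """Run simulate -> filter -> test/cluster -> kinetics -> nCounter -> align.

    ``config`` holds one section per stage (``stsilac``, ``pcsilac``,
    ``nanostring``), each either ``{"simulate": {...config fields...}}``
    or ``{"input": path}``; plus optional top-level ``seed``, ``alpha``
    and ``lab_contaminants``.  Writes all tables under ``outdir`` and
    returns the run-log dict (also written as ``run_log.json``).
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in _REQUIRED_STAGES:
        section = config.get(stage)
        if not section or not ("simulate" in section or "input" in section):
            raise ValueError(
                f"stage {stage!r}: missing 'simulate' or 'input' section"
            )
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    log: dict = {"seed": seed, "version": __version__, "stages": {}}

    # --- stSILAC -----------------------------------------------------------
    sec = config["stsilac"]
    if "simulate" in sec:
        cfg = simulate.SilacSimConfig(**{"seed": seed, **sec["simulate"]})
        table, truth = simulate.generate_stsilac_table(cfg)
        silac.write_protein_groups(table, outdir / "stsilac_raw.tsv")
        truth.to_csv(outdir / "stsilac_truth.tsv", sep="\t")
        swap = sorted(cfg.swapped_replicates)
    else:
        swap = sec.get("label_swap", [])
    table = silac.read_protein_groups(
        outdir / "stsilac_raw.tsv" if "simulate" in sec else sec["input"],
        label_swap_map=swap,
    )
    lab_list = set(config.get("lab_contaminants", []))
    filtered, report = silac.filter_quality(table, lab_list)
    silac.write_protein_groups(filtered, outdir / "stsilac_filtered.tsv")
    log["stages"]["filter"] = report.to_dict()

    occurring = silac.filter_occurrence(filtered)
    tested = differential.cluster_proteins(occurring, alpha=alpha)
    tested.to_csv(outdir / "stsilac_clusters.tsv", sep="\t", index=False)
    log["stages"]["cluster"] = {
        "tested": len(tested),
        "significant": int(tested["significant_any"].sum()),
    }

    nodes = export_node_attributes(tested, occurring.timepoints, alpha)
    nodes.to_csv(outdir / "node_attributes.tsv", sep="\t", index=False)

    # --- pcSILAC -----------------------------------------------------------
    sec = config["pcsilac"]
    if "simulate" in sec:
        preset = simulate.PcSilacPreset(**{"seed": seed + 1, **sec["simulate"]})
        series, ktruth = simulate.generate_pcsilac_series(preset)
        kinetics.write_series_csv(series, outdir / "pcsilac_series.csv")
        ktruth.to_csv(outdir / "pcsilac_truth.tsv", sep="\t")
        categories = {
            name: grp.index.tolist()
            for name, grp in ktruth.groupby("category")
            if name
        }
    else:
        series = kinetics.read_series_csv(sec["input"])
        categories = {}
    fits = kinetics.add_adjusted_columns(kinetics.fit_all(series))
    fits.to_csv(outdir / "kinetic_fits.tsv", sep="\t")
    summaries = kinetics.summarize_category(fits, categories)
    pd.DataFrame([vars(s) for s in summaries]).to_csv(
        outdir / "category_summaries.tsv", sep="\t", index=False
    )
    log["stages"]["kinetics"] = {
        "fitted": len(fits),
        "median_kd_ratio": float(2.0 ** np.median(fits["log2_kd_ratio"])),
        "median_vs_ratio": float(2.0 ** np.median(fits["log2_vs_ratio"])),
    }

    # --- nCounter ----------------------------------------------------------
    sec = config["nanostring"]
    if "simulate" in sec:
        ncfg = simulate.NanoSimConfig(**{"seed": seed + 2, **sec["simulate"]})
        dataset, ntruth = simulate.generate_nanostring_counts(ncfg)
        ntruth.to_csv(outdir / "nanostring_truth.tsv", sep="\t")
    else:
        dataset = nanostring.read_counts_csv(sec["input"], sec["samples"])
    corrected = nanostring.background_correct(dataset)
    qc_pass, qc_ratio = nanostring.qc_positive_controls(corrected)
    gen = nanostring.genorm_select(
        corrected, k=int(sec.get("k_ref", min(12, len(corrected.probes("ref")))))
    )
    normalized = nanostring.normalize_counts(corrected, gen.selected)
    fc = nanostring.fold_changes(normalized)
    fc.rename_axis("gene").to_csv(outdir / "nanostring_fc.tsv", sep="\t")
    log["stages"]["nanostring"] = {
        "qc_pass": bool(qc_pass),
        "qc_ratio": float(qc_ratio),
        "references": gen.selected,
    }

    # --- alignment ---------------------------------------------------------
    kin_table = fits.reset_index().rename(columns={"protein_id": "group_ids"})
    joint = align_datasets(tested, kin_table, suffixes=("_st", "_kin"))
    joint.to_csv(outdir / "joint_table.tsv", sep="\t", index=False)
    log["stages"]["align"] = {
        "rows": len(joint),
        "matched": int(
            joint.filter(like="cluster").notna().any(axis=1).sum()
            if "cluster_st" in joint
            else 0
        ),
    }

    log["elapsed_s"] = round(time.time() - t0, 3)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    print(f"pipeline complete: {outdir}", file=sys.stderr)
    return log
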