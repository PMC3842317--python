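import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hsp90flux.silac import ProteinGroupTable


def make_table(rows, replicates=(1, 2, 3), timepoints=(6, 20)):
    """Build a ProteinGroupTable from compact row dicts.

    Each row: {"id": ..., "ratios": {(r, t): value}, "evidence": {(r, t): n},
    "contaminant": bool, "reverse": bool}.  Missing ratios stay absent;
    missing evidence defaults to 2 wherever a ratio is present.
    """
    recs = []
    for row in rows:
        rec = {
            "group_ids": row["id"],
            "gene_name": row.get("gene", row["id"]),
            "is_contaminant": row.get("contaminant", False),
            "is_reverse": row.get("reverse", False),
        }
        for t in timepoints:
            for r in replicates:
                ratio = row.get("ratios", {}).get((r, t), np.nan)
                rec[f"ratio_r{r}_t{t}"] = ratio
                default_ev = 2 if np.isfinite(ratio) else 0
                rec[f"evidence_r{r}_t{t}"] = row.get("evidence", {}).get(
                    (r, t), default_ev
                )
        recs.append(rec)
    return ProteinGroupTable(pd.DataFrame(recs), replicates, timepoints)


@pytest.fixture
def simple_table():
    """Three clean proteins quantified everywhere."""
    rows = []
    for i, base in enumerate((2.0, 1.0, 0.5), start=1):
        ratios = {(r, t): base for r in (1, 2, 3) for t in (6, 20)}
        rows.append({"id": f"P{i}", "ratios": ratios})
    return make_table(rows)
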