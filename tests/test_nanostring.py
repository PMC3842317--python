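import numpy as np
import pandas as pd
import pytest

from hsp90flux.nanostring import (
    NanoStringDataset,
    background_correct,
    fold_changes,
    genorm_m_values,
    genorm_select,
    normalize_counts,
    qc_positive_controls,
    read_counts_csv,
)
from hsp90flux.simulate import NanoSimConfig, generate_nanostring_counts

from oracles import genorm_m_bruteforce


def build_dataset(counts: dict, classes: dict, conditions: dict):
    frame = pd.DataFrame(counts).T  # probes x samples
    frame.columns = list(conditions)
    return NanoStringDataset(
        frame.astype(float),
        pd.Series(classes),
        pd.Series(conditions),
    )


@pytest.fixture
def tiny():
    samples = {"c1": "DMSO", "c2": "DMSO", "g1": "GA", "g2": "GA"}
    counts = {
        "NEG_1": [2, 2, 2, 2],
        "NEG_2": [4, 4, 4, 4],
        "NEG_3": [6, 6, 6, 6],
        "POS_1": [100, 100, 100, 100],
        "POS_2": [200, 200, 200, 200],
        "REF_1": [50, 50, 50, 50],
        "REF_2": [80, 80, 80, 80],
        "REF_3": [120, 120, 120, 120],
        "TGT_1": [108, 108, 208, 208],
        "TGT_2": [58, 58, 58, 58],
    }
    classes = {k: k[:3].lower().replace("tgt", "target") for k in counts}
    return build_dataset(counts, classes, samples)


class TestBackgroundCorrect:
    def test_threshold_subtraction(self, tiny):
        # negatives (2,4,6): mean 4, sd 2 -> threshold 8
        out = background_correct(tiny)
        assert out.counts.loc["TGT_1", "c1"] == pytest.approx(100.0)
        assert out.counts.loc["TGT_2", "c1"] == pytest.approx(50.0)

    def test_floor_at_one(self, tiny):
        tiny.counts.loc["TGT_2"] = 5.0
        out = background_correct(tiny)
        assert (out.counts.loc["TGT_2"] == 1.0).all()

    def test_zero_negatives_zero_threshold(self, tiny):
        tiny.counts.loc[["NEG_1", "NEG_2", "NEG_3"]] = 0.0
        tiny.counts.loc["TGT_2"] = 0.0
        out = background_correct(tiny)
        assert (out.counts.loc["TGT_2"] == 1.0).all()  # 0 - 0 < 1 -> 1
        assert out.counts.loc["TGT_1", "c1"] == pytest.approx(108.0)

    def test_controls_untouched(self, tiny):
        out = background_correct(tiny)
        assert (out.counts.loc["POS_1"] == 100.0).all()
        assert (out.counts.loc["NEG_1"] == 2.0).all()


class TestQcPositiveControls:
    def test_pass_below_three(self, tiny):
        ok, ratio = qc_positive_controls(tiny)
        assert ok and ratio == pytest.approx(1.0)

    def test_ratio_arithmetic(self, tiny):
        tiny.counts.loc[["POS_1", "POS_2"], "g2"] *= 2.5
        ok, ratio = qc_positive_controls(tiny)
        assert ok and ratio == pytest.approx(2.5)

    def test_fail_at_three_and_a_half(self, tiny):
        tiny.counts.loc[["POS_1", "POS_2"], "g2"] *= 3.5
        ok, ratio = qc_positive_controls(tiny)
        assert not ok and ratio == pytest.approx(3.5)

    def test_zero_mean_fails_infinite(self, tiny):
        tiny.counts.loc[["POS_1", "POS_2"], "c1"] = 0.0
        ok, ratio = qc_positive_controls(tiny)
        assert not ok and ratio == np.inf


class TestGeNorm:
    def test_proportional_candidates_m_zero(self):
        logs = pd.DataFrame(
            {
                "s1": [1.0, 2.0],
                "s2": [3.0, 4.0],
                "s3": [0.0, 1.0],
            },
            index=["REF_1", "REF_2"],
        )
        m = genorm_m_values(logs)
        assert m.to_numpy() == pytest.approx([0.0, 0.0])

    def test_noisy_candidate_ranked_last(self, tiny):
        rng = np.random.default_rng(0)
        tiny.counts.loc["REF_3"] *= np.exp(rng.normal(0, 0.5, 4))
        corrected = background_correct(tiny)
        result = genorm_select(corrected, k=2)
        assert result.ranking[-1] == "REF_3"
        assert set(result.selected) == {"REF_1", "REF_2"}

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        logs = pd.DataFrame(
            rng.normal(8, 1, size=(6, 5)),
            index=[f"REF_{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(5)],
        )
        ours = genorm_m_values(logs)
        brute = genorm_m_bruteforce(
            {g: list(logs.loc[g]) for g in logs.index}
        )
        for g in logs.index:
            assert ours[g] == pytest.approx(brute[g], rel=1e-12)

    def test_identical_samples_select_first_k(self, tiny):
        corrected = background_correct(tiny)
        result = genorm_select(corrected, k=2)
        assert result.selected == ["REF_1", "REF_2"]

    def test_fewer_candidates_than_k_warns(self, tiny):
        corrected = background_correct(tiny)
        with pytest.warns(UserWarning):
            result = genorm_select(corrected, k=12)
        assert set(result.selected) == {"REF_1", "REF_2", "REF_3"}

    def test_zero_counts_rejected(self, tiny):
        tiny.counts.loc["REF_1", "c1"] = 0.0
        with pytest.raises(ValueError, match="background"):
            genorm_select(tiny, k=2)


class TestNormalize:
    def test_geometric_mean_factor(self, tiny):
        # sample c1 references scaled so its factor is sqrt(4*9)=6x others
        refs = ["REF_1", "REF_2", "REF_3"]
        out = normalize_counts(tiny, refs)
        ref_geomeans = np.exp(np.log(out.counts.loc[refs]).mean(axis=0))
        assert ref_geomeans.to_numpy() == pytest.approx(
            np.full(4, ref_geomeans.iloc[0])
        )

    def test_equal_factors_leave_counts(self, tiny):
        out = normalize_counts(tiny, ["REF_1", "REF_2", "REF_3"])
        pd.testing.assert_frame_equal(out.counts, tiny.counts)

    def test_global_scaling_invariance(self, tiny):
        doubled = tiny.with_counts(
            tiny.counts.mul(
                pd.Series([2.0, 1, 1, 1], index=tiny.counts.columns), axis=1
            )
        )
        a = normalize_counts(tiny, ["REF_1", "REF_2"])
        b = normalize_counts(doubled, ["REF_1", "REF_2"])
        targets = ["TGT_1", "TGT_2"]
        # identical up to one common anchor factor; fold-changes identical
        ratio = (b.counts.loc[targets] / a.counts.loc[targets]).to_numpy()
        assert ratio == pytest.approx(np.full_like(ratio, ratio.flat[0]))
        pd.testing.assert_series_equal(fold_changes(a), fold_changes(b))

    def test_zero_reference_rejected(self, tiny):
        tiny.counts.loc["REF_1", "c1"] = 0.0
        with pytest.raises(ValueError):
            normalize_counts(tiny, ["REF_1", "REF_2"])


class TestFoldChanges:
    def test_geomean_ratio(self):
        samples = {"c1": "DMSO", "c2": "DMSO", "g1": "GA", "g2": "GA"}
        counts = {
            "NEG_1": [1, 1, 1, 1],
            "NEG_2": [1, 1, 1, 1],
            "POS_1": [10, 10, 10, 10],
            "POS_2": [10, 10, 10, 10],
            "TGT_1": [1, 4, 2, 8],  # geomeans 2 and 4 -> log2 FC 1
        }
        classes = {k: k[:3].lower().replace("tgt", "target") for k in counts}
        ds = build_dataset(counts, classes, samples)
        fc = fold_changes(ds)
        assert fc["TGT_1"] == pytest.approx(1.0)

    def test_identical_conditions_zero(self, tiny):
        fc = fold_changes(tiny)
        assert fc["TGT_2"] == pytest.approx(0.0)

    def test_label_swap_antisymmetry(self, tiny):
        fc = fold_changes(tiny)
        swapped = NanoStringDataset(
            tiny.counts,
            tiny.probe_class,
            tiny.condition.map({"GA": "DMSO", "DMSO": "GA"}),
        )
        fc_swapped = fold_changes(swapped)
        assert fc_swapped.to_numpy() == pytest.approx(-fc.to_numpy())

    def test_requires_both_conditions(self, tiny):
        only = NanoStringDataset(
            tiny.counts,
            tiny.probe_class,
            pd.Series("DMSO", index=tiny.counts.columns),
        )
        with pytest.raises(ValueError):
            fold_changes(only)


class TestPipelineRecovery:
    def test_zero_noise_exact(self):
        fc_map = {"TGT_1": 1.5, "TGT_2": -2.0}
        cfg = NanoSimConfig(
            n_targets=10, count_noise_logsd=0.0, fold_change_map=fc_map,
            seed=5,
        )
        ds, truth = generate_nanostring_counts(cfg)
        corrected = background_correct(ds)
        ok, _ = qc_positive_controls(corrected)
        assert ok
        sel = genorm_select(corrected, k=12)
        normalized = normalize_counts(corrected, sel.selected)
        fc = fold_changes(normalized)
        for gene, expected in truth.items():
            assert fc[gene] == pytest.approx(expected, abs=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(9)
        fc_map = {f"TGT_{i + 1}": float(rng.normal(0, 1)) for i in range(30)}
        cfg = NanoSimConfig(
            n_targets=88, count_noise_logsd=0.1, fold_change_map=fc_map,
            seed=4,
        )
        ds, truth = generate_nanostring_counts(cfg)
        corrected = background_correct(ds)
        sel = genorm_select(corrected, k=12)
        normalized = normalize_counts(corrected, sel.selected)
        fc = fold_changes(normalized)
        err = np.abs(fc.loc[truth.index] - truth)
        assert (err <= 0.2).mean() >= 0.95

    def test_csv_roundtrip(self, tmp_path, tiny):
        counts_path = tmp_path / "counts.csv"
        samples_path = tmp_path / "samples.csv"
        frame = tiny.counts.copy()
        frame.insert(0, "class", tiny.probe_class)
        frame.rename_axis("probe").to_csv(counts_path)
        pd.DataFrame(
            {"sample": tiny.counts.columns,
             "condition": tiny.condition.to_numpy()}
        ).to_csv(samples_path, index=False)
        back = read_counts_csv(counts_path, samples_path)
        pd.testing.assert_frame_equal(
            back.counts, tiny.counts, check_names=False
        )
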