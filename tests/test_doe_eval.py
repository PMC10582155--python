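import itertools
import math

import numpy as np
import pytest

from avfsound.doe_eval import (
    SAMPEN_GRID,
    Metrics,
    estimate_effects,
    fractional_factorial_2k1,
    full_factorial,
    metrics_from_confusion,
    repeated_evaluation,
    run_sampen_doe,
    summarize_repeats,
)


class TestFullFactorial:
    def test_study_grid_enumerates_1215_runs(self):
        design = full_factorial(SAMPEN_GRID)
        assert design.n_runs == 1215
        assert design.runs.drop_duplicates().shape[0] == 1215

    def test_single_factor_single_level(self):
        assert full_factorial({"a": [1]}).n_runs == 1

    def test_two_by_three(self):
        design = full_factorial({"a": [0, 1], "b": [0, 1, 2]})
        assert design.n_runs == 6
        assert design.runs.drop_duplicates().shape[0] == 6

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError):
            full_factorial({"a": []})


class TestFractionalFactorial:
    def test_sixteen_balanced_runs(self):
        design = fractional_factorial_2k1(5)
        assert design.n_runs == 16
        for col in design.factor_names:
            assert (design.runs[col] == 1).sum() == 8
            assert (design.runs[col] == -1).sum() == 8

    def test_defining_relation_holds(self):
        design = fractional_factorial_2k1(5)
        assert design.defining_relation == "I=ABCDE"
        prod = design.runs[["A", "B", "C", "D"]].prod(axis=1)
        assert (design.runs["E"] == prod).all()

    def test_main_effect_columns_orthogonal(self):
        design = fractional_factorial_2k1(5)
        cols = design.runs[design.factor_names].to_numpy()
        gram = cols.T @ cols
        assert np.array_equal(gram, 16 * np.eye(5))

    def test_resolution_v_alias_structure(self):
        # each main effect aliases only the complementary 4-factor interaction
        design = fractional_factorial_2k1(5)
        runs = design.runs
        for factor in design.factor_names:
            others = [f for f in design.factor_names if f != factor]
            assert (runs[factor] == runs[others].prod(axis=1)).all()
            # and no 2- or 3-factor word collapses onto it
            for k in (2, 3):
                for combo in itertools.combinations(others, k):
                    assert not (runs[factor] == runs[list(combo)].prod(axis=1)).all()


class TestEstimateEffects:
    def test_noiseless_planted_response_recovered(self):
        design = fractional_factorial_2k1(5)
        y = 3.0 + 2.0 * design.runs["C"].to_numpy(dtype=float)
        table = estimate_effects(design, y)
        assert table["C"]["effect"] == pytest.approx(4.0, abs=1e-12)
        assert table["C"]["coef"] == pytest.approx(2.0, abs=1e-12)
        for term in ("A", "B", "D", "E", "B*D"):
            assert table[term]["effect"] == pytest.approx(0.0, abs=1e-12)

    def test_coef_is_half_effect_for_every_term(self):
        design = fractional_factorial_2k1(5)
        rng = np.random.default_rng(0)
        y = rng.uniform(0.7, 0.95, size=32)
        table = estimate_effects(design, y, replicates=2).table
        np.testing.assert_allclose(table["coef"], table["effect"] / 2.0, rtol=0, atol=1e-15)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        design = fractional_factorial_2k1(5)
        rng = np.random.default_rng(1)
        y = rng.uniform(0.7, 0.95, size=32)
        table = estimate_effects(design, y, replicates=2)
        X = design.runs[design.factor_names].to_numpy(dtype=float)
        X = np.column_stack([X, X[:, 1] * X[:, 3]])  # B*D
        X = np.tile(X, (2, 1))
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for i, term in enumerate(["A", "B", "C", "D", "E", "B*D"]):
            row = table[term]
            assert row["coef"] == pytest.approx(fit.params[i + 1], rel=1e-9)
            assert row["t_value"] == pytest.approx(fit.tvalues[i + 1], rel=1e-9)
            assert row["p_value"] == pytest.approx(fit.pvalues[i + 1], rel=1e-9)

    def test_constant_response_flags_undefined_tests(self):
        design = fractional_factorial_2k1(5)
        table = estimate_effects(design, np.full(16, 0.5))
        assert np.allclose(table.table["effect"], 0.0)
        assert table.table["p_value"].isna().all()

    def test_saturated_model_without_replicates_rejected(self):
        design = fractional_factorial_2k1(3)  # 4 runs
        with pytest.raises(ValueError, match="degrees of freedom"):
            estimate_effects(design, np.zeros(4),
                             interactions=[("A", "B"), ("A", "C"), ("B", "C")])

    def test_wrong_response_length_rejected(self):
        design = fractional_factorial_2k1(5)
        with pytest.raises(ValueError, match="responses"):
            estimate_effects(design, np.zeros(10))


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_confusion(5, 0, 5, 0)
        assert m.as_dict() == {"sensitivity": 1.0, "specificity": 1.0,
                               "accuracy": 1.0, "precision": 1.0, "f1": 1.0}

    def test_all_positive_predictor(self):
        m = metrics_from_confusion(5, 5, 0, 0)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.accuracy == 0.5
        assert m.precision == 0.5
        assert m.f1 == pytest.approx(2 / 3)

    def test_undefined_precision_is_missing_not_zero(self):
        m = metrics_from_confusion(0, 0, 5, 5)
        assert m.precision is None
        assert m.f1 is None
        assert m.accuracy == 0.5

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(0, 0, 0, 0)

    def test_identities_hold_exhaustively(self):
        # F1 = 2PR/(P+R) and accuracy = (sen*P + spe*N)/(P+N), all totals <= 12
        for tp, fp, tn, fn in itertools.product(range(13), repeat=4):
            total = tp + fp + tn + fn
            if total == 0 or total > 12:
                continue
            m = metrics_from_confusion(tp, fp, tn, fn)
            if m.precision is not None and m.sensitivity is not None and m.f1 is not None:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.sensitivity / (m.precision + m.sensitivity))
            pos, neg = tp + fn, tn + fp
            if pos and neg:
                assert m.accuracy == pytest.approx(
                    (m.sensitivity * pos + m.specificity * neg) / total)


class TestSummaries:
    def test_identical_repeats_give_zero_se(self):
        reps = [metrics_from_confusion(4, 1, 4, 1)] * 5
        s = summarize_repeats(reps)
        assert s.se_accuracy == 0.0
        assert s.accuracy == pytest.approx(0.8)
        assert s.n_repeats == 5

    def test_se_scales_inverse_sqrt_n(self):
        # alternating streams scaled so the ddof-1 sample sd is the same
        # (0.01) at both lengths: SE(16) must then be exactly SE(4)/2
        def stream(n):
            half_spread = 0.01 * math.sqrt((n - 1) / n)
            return [Metrics(sensitivity=0.9 + half_spread * (-1) ** i, specificity=None,
                            accuracy=None, precision=None, f1=None)
                    for i in range(n)]

        se4 = summarize_repeats(stream(4)).se_sensitivity
        se16 = summarize_repeats(stream(16)).se_sensitivity
        assert se16 == pytest.approx(se4 / 2)

    def test_single_repeat_rejected(self, desk_dataset):
        from avfsound.classifier import ModelConfig

        with pytest.raises(ValueError, match="n_repeats"):
            repeated_evaluation(desk_dataset, ModelConfig(), n_repeats=1)


@pytest.fixture(scope="module")
def labeled_cycles():
    # several recordings per class, so a threshold must generalize
    # across recordings rather than memorize one recording's quirks
    import avfsound as av
    from avfsound import pipeline

    cycles = []
    for i in range(4):
        for label, seed in (("stenosis", 11 + i), ("normal", 31 + i)):
            rec = av.generate_recording(
                av.SimConfig(duration_s=10.0, severity=0.8, snr_db=15.0, seed=seed),
                label)
            rec.label = label
            cycles += pipeline.preprocess_recording(rec, filtering="EMD")
    return cycles


class TestModelDOE:
    def test_screening_runs_and_effect_table(self):
        from avfsound.classifier import ModelConfig
        from avfsound.doe_eval import run_model_doe
        from avfsound.pipeline import CycleDataset

        rng = np.random.default_rng(0)
        n_pat, per = 12, 6
        n = n_pat * per
        labels = np.repeat(np.arange(n_pat) % 2, per)
        pids = np.repeat([f"P{i:02d}" for i in range(n_pat)], per)
        images = rng.uniform(0, 0.2, size=(n, 16, 16, 3))
        images[labels == 1, :8] += 0.6
        feats = rng.standard_normal((n, 3)) + 2.5 * labels[:, None]
        ds = CycleDataset(images=images, features=feats, labels=labels,
                          patient_ids=pids)
        base = ModelConfig(resnet_variant="reduced", image_size_px=16, epochs=2,
                           batch_size=16, learning_rate=1e-3)
        design, runs, effects = run_model_doe(ds, base, n_repeats=1, seed=0)
        assert design.n_runs == 16
        assert len(runs) == 16
        assert runs["accuracy"].between(0, 1).all()
        assert list(effects.table["term"]) == ["A", "B", "C", "D", "E", "B*D"]
        np.testing.assert_allclose(effects.table["coef"],
                                   effects.table["effect"] / 2.0, atol=1e-15)


class TestSampEnDOE:
    def test_bands_covering_bruit_outrank_disjoint_bands(self, labeled_cycles):
        grid = {"F_L": [10], "F_H": [90, 1000], "m": [2], "r": [0.2]}
        for seed in range(5):
            table = run_sampen_doe(labeled_cycles, grid=grid, split_seed=seed)
            by_band = table.set_index("F_H")
            assert by_band.loc[1000, "accuracy"] > by_band.loc[90, "accuracy"]
            assert table.iloc[0]["F_H"] == 1000

    def test_single_point_grid(self, labeled_cycles):
        table = run_sampen_doe(
            labeled_cycles, grid={"F_L": [10], "F_H": [700], "m": [4], "r": [0.2]})
        assert len(table) == 1
        assert set(["rank", "F_L", "F_H", "m", "r", "sensitivity",
                    "specificity", "accuracy"]) <= set(table.columns)

    def test_single_class_rejected(self, labeled_cycles):
        only_s = [c for c in labeled_cycles if c.label == "stenosis"]
        with pytest.raises(ValueError, match="both classes"):
            run_sampen_doe(only_s, grid={"F_L": [10], "F_H": [700], "m": [2], "r": [0.2]})
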