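"""Metrics, fold construction, and the cross-validated variant comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import r2_score

from nutrispec import (
    Calibration,
    Dataset,
    TrainConfig,
    estimate,
    evaluate_variants,
    kfold_indices,
    predict_with_rejection,
    r2,
    simulate_ood_food,
    smape,
)
from nutrispec.evaluation import UndefinedMetricError, best_models_smape
from nutrispec.spectra import SpectraError


class TestKfold:
    def test_n_equals_k_gives_singletons(self):
        folds = kfold_indices(10, 10, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = kfold_indices(25, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2] * 5 + [3] * 5

    @given(st.integers(2, 40), st.integers(2, 10), st.integers(0, 100))
    def test_partition_property(self, n, k, seed):
        if k > n:
            k = n
        folds = kfold_indices(n, k, seed)
        flat = np.concatenate(folds)
        assert len(flat) == n
        assert set(flat.tolist()) == set(range(n))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self):
        a = kfold_indices(30, 5, seed=9)
        b = kfold_indices(30, 5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_invalid_k(self):
        with pytest.raises(SpectraError):
            kfold_indices(5, 1)
        with pytest.raises(SpectraError):
            kfold_indices(5, 6)


class TestR2:
    def test_perfect_fit(self):
        assert r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        assert r2([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert r2([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            r2([2, 2, 2], [1, 2, 3])

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            t = rng.normal(10, 5, size=30)
            p = t + rng.normal(0, 2, size=30)
            assert r2(t, p) == pytest.approx(r2_score(t, p), rel=1e-12)


class TestSmape:
    def test_perfect_fit_is_zero(self):
        assert smape([1.0, 5.0], [1.0, 5.0]) == 0.0

    def test_hand_example(self):
        assert smape([10.0], [5.0]) == pytest.approx(2 * 5 / 15)

    def test_zero_pairs_contribute_nothing(self):
        assert smape([0.0, 10.0], [0.0, 10.0]) == 0.0

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=20), st.data())
    def test_bounded_in_zero_two(self, t, data):
        p = data.draw(st.lists(st.floats(0, 1e6), min_size=len(t),
                               max_size=len(t)))
        v = smape(t, p)
        assert 0.0 <= v <= 2.0

    def test_matches_elementwise_oracle(self, rng):
        t = rng.uniform(0, 100, size=50)
        p = rng.uniform(0, 100, size=50)
        oracle = np.mean([2 * abs(a - b) / (abs(a) + abs(b))
                          for a, b in zip(p, t)])
        assert smape(t, p) == pytest.approx(oracle, rel=1e-14)


@pytest.fixture(scope="module")
def small_report(small_dataset, fwd_model):
    rng = np.random.default_rng(29)
    ood = [simulate_ood_food(fwd_model, 1.0, rng=rng, sample_id=f"ood{i}")
           for i in range(20)]
    configs = {
        "multimodal": TrainConfig(variant="multimodal", epochs=300, seed=0),
        "proposed": TrainConfig(variant="proposed", epochs=300,
                                loss_weights=(30.0, 1.0, 1.0, 1.0), seed=0),
    }
    return evaluate_variants(small_dataset, configs, k=4, seed=1,
                             contamination=0.2, ood_foods=ood)


class TestEvaluateVariants:
    def test_every_food_predicted_exactly_once(self, small_report,
                                               small_dataset):
        for variant in ("multimodal", "proposed"):
            ids = [r["sample_id"] for r in small_report.records[variant]
                   if not r["is_ood"]]
            assert sorted(ids) == sorted(s.sample_id
                                         for s in small_dataset.samples)

    def test_contamination_fraction_in_test_folds(self, small_report):
        recs = small_report.records["multimodal"]
        n_ood = sum(r["is_ood"] for r in recs)
        assert n_ood / len(recs) == pytest.approx(0.2, abs=0.05)

    def test_rejection_rate_reported_and_bounded(self, small_report):
        rr = small_report.variants["proposed"]["rejection_rate"]
        assert 0.0 <= rr <= 1.0

    def test_accepted_subset_smape_dominates(self, small_report):
        """Selective prediction helps: per-nutrient SMAPE over accepted
        predictions is no worse than over all predictions."""
        from nutrispec import NUTRIENTS
        recs = small_report.records["proposed"]
        for i, _ in enumerate(NUTRIENTS):
            t_all = np.array([r["truth"][i] for r in recs])
            p_all = np.array([r["pred"][i] for r in recs])
            used = [r for r in recs if r["accepted"]]
            t_acc = np.array([r["truth"][i] for r in used])
            p_acc = np.array([r["pred"][i] for r in used])
            assert smape(t_acc, p_acc) <= smape(t_all, p_all) + 1e-12

    def test_report_serializes(self, small_report, tmp_path):
        small_report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").stat().st_size > 0

    def test_contamination_requires_ood_pool(self, small_dataset):
        with pytest.raises(SpectraError):
            evaluate_variants(
                small_dataset,
                {"multimodal": TrainConfig(variant="multimodal", epochs=1)},
                k=4, contamination=0.2)


class TestSelectiveIdentity:
    def test_infinite_tau_makes_proposed_equal_multimodal_predictions(
            self, trained_multimodal, train_test_split):
        """With tau = +inf the selective-prediction wrapper is a no-op: it
        accepts everything and reports exactly the plain estimates."""
        _, test = train_test_split
        cal = Calibration.fixed(np.inf)
        for f in test:
            s = f.mean_spectrum()
            res = predict_with_rejection(trained_multimodal, s, cal)
            assert res.accepted
            assert res.composition == estimate(trained_multimodal, s)


class TestBestModels:
    def test_ranks_restarts_by_training_loss(self, small_dataset):
        configs = {"multimodal": TrainConfig(variant="multimodal", epochs=15,
                                             seed=0)}
        reports = []
        for r in range(3):
            cfg = {"multimodal": TrainConfig(variant="multimodal", epochs=15,
                                             seed=r)}
            reports.append(evaluate_variants(small_dataset, cfg, k=3, seed=1))
        out = best_models_smape(reports, "multimodal", top_k=2)
        assert out["top_k"] == 2 and out["n_restarts"] == 3
        for nutrient in ("carbohydrate", "protein", "fat"):
            assert out[nutrient] is None or out[nutrient] >= 0
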