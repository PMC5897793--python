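"""GP classifier: fitting, prediction, CV partitioning, metrics,
persistence."""

import dataclasses

import numpy as np
import pytest

from orfscreen import (FeatureVector, LabeledSample, Prediction,
                       calibration_curve, cross_validate, fit, fold_sizes,
                       load_model, pr_curve, roc_auc, save_model)
from orfscreen.model import ModelFormatError, _fit_xy


def _fv(f1, f2=1.0, f3=4.0):
    return FeatureVector(f1=f1, f2=f2, f3=f3, n_stops=0, n_aligned_aa=1,
                         n_hits=1)


def two_clusters(delta_f1=4.0, n=50, seed=1, sigma=0.5):
    """Two Gaussian clusters separated along f1; spurious sits higher."""
    rng = np.random.default_rng(seed)
    samples = []
    for label, centre in (("real", -6.0), ("spurious", -6.0 + delta_f1)):
        for i in range(n):
            samples.append(LabeledSample(
                _fv(centre + sigma * rng.standard_normal(),
                    2.0 + sigma * rng.standard_normal(),
                    4.0 + sigma * rng.standard_normal()),
                label, f"{label}{i}"))
    return samples


class TestFit:
    def test_separable_clusters_reach_perfect_training_accuracy(self):
        samples = two_clusters(delta_f1=4.0, n=50, seed=1)
        m = fit(samples, seed=1)
        X = np.array([s.features.as_tuple() for s in samples])
        y = np.array([s.label == "spurious" for s in samples])
        assert (((m.predict_proba(X) >= 0.5) == y).mean()) == 1.0

    def test_single_class_rejected(self):
        samples = [LabeledSample(_fv(-6 + 0.1 * i), "real", str(i))
                   for i in range(10)]
        with pytest.raises(ValueError, match="single class"):
            fit(samples, seed=0)

    def test_non_finite_feature_names_the_sample(self):
        samples = two_clusters(n=5)
        samples[3] = dataclasses.replace(
            samples[3], features=_fv(float("nan")))
        with pytest.raises(ValueError, match=samples[3].source_id):
            fit(samples, seed=0)

    def test_duplicating_samples_barely_moves_predictions(self):
        samples = two_clusters(n=30, seed=4)
        m1 = fit(samples, seed=1)
        m2 = fit(samples + samples, seed=1)
        grid = np.column_stack([
            np.linspace(-8, 0, 50),
            np.full(50, 2.0), np.full(50, 4.0)])
        assert np.abs(m1.predict_proba(grid)
                      - m2.predict_proba(grid)).max() < 0.1


class TestPredict:
    def test_deep_inside_spurious_cluster_scores_high(self):
        samples = two_clusters(delta_f1=4.0, n=50, seed=1)
        m = fit(samples, seed=1)
        p = m.predict(_fv(-2.0, 2.0, 4.0), query_id="probe")
        assert p.p_spurious > 0.9
        assert p.call == "spurious"

    def test_midpoint_of_symmetric_clusters_is_uncertain(self):
        samples = two_clusters(delta_f1=4.0, n=50, seed=1)
        m = fit(samples, seed=1)
        p = m.predict(_fv(-4.0, 2.0, 4.0), query_id="mid", threshold=0.5)
        assert 0.4 <= p.p_spurious <= 0.6

    def test_threshold_is_at_or_above(self):
        samples = two_clusters(delta_f1=4.0, n=30, seed=2)
        m = fit(samples, seed=1)
        p = m.predict(_fv(-3.0, 2.0, 4.0), query_id="x")
        # exactly at the threshold: spurious; just above the score: real
        at = m.predict(_fv(-3.0, 2.0, 4.0), threshold=p.p_spurious)
        above = m.predict(_fv(-3.0, 2.0, 4.0),
                          threshold=p.p_spurious + 1e-9)
        assert at.call == "spurious"
        assert above.call == "real"

    def test_no_homologs_is_a_no_call_not_a_score(self):
        samples = two_clusters(n=10)
        m = fit(samples, seed=0)
        p = m.predict(None, query_id="orphan")
        assert p == Prediction("orphan", None, "no_call", 0.8)


class TestCrossValidation:
    def test_balanced_3107_per_class_with_8_folds(self):
        sizes = fold_sizes(2 * 3107, k=8)
        test_sizes = [t for _, t in sizes]
        assert min(test_sizes) == 776
        assert dict(sizes)[5438] == 776
        assert sum(test_sizes) == 6214

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            fold_sizes(5, 8)
        with pytest.raises(ValueError):
            cross_validate(two_clusters(n=2), k=8, seed=0)

    def test_tiny_separable_cv_is_perfect(self):
        samples = two_clusters(delta_f1=6.0, n=8, seed=3, sigma=0.2)
        rep = cross_validate(samples, k=8, seed=0)
        assert rep.mean_test_accuracy == 1.0
        assert rep.k == 8

    def test_every_sample_tested_exactly_once(self):
        samples = two_clusters(n=13, seed=5)
        rep = cross_validate(samples, k=4, seed=1)
        assert np.isfinite(rep.oof_scores).all()
        assert sum(f.test_n for f in rep.folds) == len(samples)

    def test_folds_are_stratified(self):
        samples = two_clusters(n=20, seed=6)
        rep = cross_validate(samples, k=8, seed=2)
        # balanced input: each fold's test size must be even within 1 sample
        # per class, i.e. test_n in {4, 6} with class split ~ half
        for f in rep.folds:
            assert f.test_n in (4, 5, 6)


class TestMetrics:
    def test_perfect_scores_give_auc_one(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_four_point_hand_computed_roc(self):
        assert roc_auc([.9, .8, .3, .1], [1, 1, 0, 0]) == 1.0
        # positives score .9 and .3: one inversion out of four pairs
        assert roc_auc([.9, .8, .3, .1], [1, 0, 1, 0]) == pytest.approx(0.75)
        assert self.mann_whitney_auc(
            [.9, .8, .3, .1], [1, 0, 1, 0]) == 0.75

    @staticmethod
    def mann_whitney_auc(scores, labels):
        """Pair-count oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_auc_equals_pair_count_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # ties likely
            assert roc_auc(scores, labels) == pytest.approx(
                self.mann_whitney_auc(scores, labels))

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=1000)
        scores = rng.random(1000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_metrics_rejected(self):
        for fn in (roc_auc, pr_curve):
            with pytest.raises(ValueError):
                fn([0.2, 0.8], [1, 1])
        with pytest.raises(ValueError):
            calibration_curve([0.2, 0.8], [1, 1])

    def test_calibration_bins_are_equal_width_with_observed_freq(self):
        scores = [0.05, 0.15, 0.15, 0.95, 0.95, 0.85]
        labels = [0, 0, 1, 1, 1, 1]
        rows = calibration_curve(scores, labels, bins=10)
        assert rows.shape[1] == 3
        by_count = {int(c): (p, f) for p, f, c in rows}
        assert rows[:, 2].sum() == 6
        assert rows[0][1] == 0.0  # lowest bin: no spurious observed
        assert rows[-1][1] == 1.0

    def test_pr_curve_reaches_full_recall(self):
        pts = pr_curve([.9, .8, .4, .2], [1, 0, 1, 0])
        assert pts[:, 0].max() == 1.0


class TestPersistence:
    def test_round_trip_predicts_identically(self, tmp_path):
        samples = two_clusters(n=25, seed=8)
        m = fit(samples, seed=1)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        loaded = load_model(path)
        rng = np.random.default_rng(0)
        grid = np.column_stack([rng.uniform(-9, -1, 100),
                                rng.uniform(0, 4, 100),
                                rng.uniform(3, 7, 100)])
        before = m.predict_proba(grid)
        after = loaded.predict_proba(grid)
        assert np.max(np.abs(before - after)) == 0.0
        assert loaded.metadata["log_base"] == "e"
        assert loaded.metadata["trim_edge_width"] == 10

    def test_missing_normalization_block_rejected(self, tmp_path):
        import joblib
        samples = two_clusters(n=10)
        m = fit(samples, seed=0)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        blob = joblib.load(path)
        del blob["normalization"]
        joblib.dump(blob, path)
        with pytest.raises(ModelFormatError, match="normalization"):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        import joblib
        samples = two_clusters(n=10)
        m = fit(samples, seed=0)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        blob = joblib.load(path)
        blob["format_version"] = 999
        joblib.dump(blob, path)
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    def test_garbage_file_rejected(self, tmp_path):
        import joblib
        path = tmp_path / "model.joblib"
        joblib.dump([1, 2, 3], path)
        with pytest.raises(ModelFormatError):
            load_model(path)


def test_fit_xy_determinism_under_seed():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int)
    p1 = _fit_xy(X, y, seed=5).predict_proba(X)
    p2 = _fit_xy(X, y, seed=5).predict_proba(X)
    assert np.array_equal(p1, p2)
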