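"""Ensemble pipeline: standardization, SMOTE, calibration, late fusion."""

import numpy as np
import pandas as pd
import pytest

from avphenotype.fusion import (
    CalibrationParams,
    EnsembleConfig,
    calibrate,
    calibration_fit,
    fit_predict_feature_set,
    fuse_multiclass,
    late_fuse,
    smote_oversample,
    zscore_fit_apply,
)

FAST = EnsembleConfig(seed=0, calibration_cv=5)


def _df(X):
    X = np.atleast_2d(X)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


class TestZscore:
    def test_population_std(self):
        tr, te = zscore_fit_apply(_df([[0.0], [2.0]]), _df([[1.0]]))
        np.testing.assert_allclose(tr.f0, [-1.0, 1.0])
        np.testing.assert_allclose(te.f0, [0.0])

    def test_constant_feature_dropped(self):
        X = _df([[0.0, 5.0], [2.0, 5.0]])
        tr, te = zscore_fit_apply(X, _df([[1.0, 5.0]]))
        assert list(tr.columns) == ["f0"]
        assert list(te.columns) == ["f0"]

    def test_train_standardized(self, rng):
        X = _df(rng.normal(3, 7, size=(40, 4)))
        tr, _ = zscore_fit_apply(X, X.iloc[:2])
        np.testing.assert_allclose(tr.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.std(ddof=0), 1.0, atol=1e-12)

    def test_unknown_test_feature_errors(self):
        with pytest.raises(ValueError, match="absent"):
            zscore_fit_apply(_df([[0.0], [1.0]]), pd.DataFrame({"g0": [1.0]}))


class TestSmote:
    def test_balanced_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        X2, y2 = smote_oversample(X, y, rng=rng)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_counts_equalized(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([0] * 22 + [1] * 8)
        _, y2 = smote_oversample(X, y, rng=rng)
        assert np.sum(y2 == 0) == np.sum(y2 == 1) == 22

    def test_synthetic_points_on_minority_segments(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 15 + [1] * 5)
        Xm = X[y == 1]
        X2, y2 = smote_oversample(X, y, k=3, rng=rng)
        for p in X2[len(X):]:
            # p = a + t(b - a) for some minority pair (a, b), t in [0, 1]
            on_segment = False
            for i in range(len(Xm)):
                for j in range(len(Xm)):
                    if i == j:
                        continue
                    d = Xm[j] - Xm[i]
                    t = np.dot(p - Xm[i], d) / np.dot(d, d)
                    if 0 <= t <= 1 and np.allclose(Xm[i] + t * d, p, atol=1e-9):
                        on_segment = True
            assert on_segment

    def test_singleton_minority_fallback(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        X2, y2 = smote_oversample(X, y, rng=rng)
        assert np.sum(y2 == 1) == 4
        np.testing.assert_allclose(X2[5:], np.tile(X[4], (3, 1)), atol=0.01)


class TestCalibration:
    def test_perfect_split(self):
        p = calibration_fit([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert p.p_thr == pytest.approx(0.5)
        assert p.p_min == pytest.approx(0.1)
        assert p.p_max == pytest.approx(0.9)

    def test_anticorrelated_smallest_candidate(self):
        """All candidates give gmean 0: the smallest wins."""
        p = calibration_fit([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert p.p_thr == pytest.approx(0.15)

    def test_exhaustive_oracle(self, rng):
        """The fitted threshold attains the max gmean over all candidates."""
        for _ in range(30):
            probs = rng.random(25)
            y = rng.integers(0, 2, 25)
            if np.unique(y).size < 2 or np.unique(probs).size < 2:
                continue
            params = calibration_fit(probs, y)
            uniq = np.unique(probs)
            cands = (uniq[:-1] + uniq[1:]) / 2

            def gmean(t):
                pred = probs >= t
                sen = np.sum(pred & (y == 1)) / np.sum(y == 1)
                spe = np.sum(~pred & (y == 0)) / np.sum(y == 0)
                return np.sqrt(sen * spe)

            best = max(gmean(t) for t in cands)
            assert gmean(params.p_thr) == pytest.approx(best)
            winners = [t for t in cands if gmean(t) == pytest.approx(best)]
            assert params.p_thr == pytest.approx(min(winners))

    def test_bounds_invariant(self, rng):
        probs = rng.random(40)
        y = rng.integers(0, 2, 40)
        p = calibration_fit(probs, y)
        assert p.p_min <= p.p_thr <= p.p_max

    def test_degenerate_single_value(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = calibration_fit([0.4, 0.4, 0.4], [0, 1, 0])
        assert p.p_thr == 0.4
        assert p.degenerate


class TestCalibrate:
    PARAMS = CalibrationParams(0.2, 0.5, 0.8)

    @pytest.mark.parametrize(
        "p,expected", [(0.5, 0.5), (0.2, 0.0), (0.8, 1.0), (0.65, 0.75), (0.35, 0.25)]
    )
    def test_piecewise_linear(self, p, expected):
        assert calibrate(p, self.PARAMS) == pytest.approx(expected)

    def test_clipping(self):
        assert calibrate(0.05, self.PARAMS) == 0.0
        assert calibrate(0.95, self.PARAMS) == 1.0

    def test_fully_degenerate_half(self):
        assert calibrate(0.7, CalibrationParams(0.3, 0.3, 0.3)) == 0.5

    def test_always_in_unit_interval(self, rng):
        raw = rng.random(100)
        out = calibrate(raw, self.PARAMS)
        assert np.all((out >= 0) & (out <= 1))


class TestFitPredict:
    def test_separable_high_accuracy(self, rng):
        """3-SD shift on 5 features, n=60: held-out balanced accuracy >= 0.95."""
        n, d = 60, 5
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(size=(n, d))
        X[y == 1] += 3.0
        Xte = rng.normal(size=(30, d))
        yte = np.array([0] * 15 + [1] * 15)
        Xte[yte == 1] += 3.0
        s = fit_predict_feature_set(_df(X), y, _df(Xte), FAST)
        pred = (s >= 0.5).astype(int)
        sen = np.mean(pred[yte == 1])
        spe = np.mean(1 - pred[yte == 0])
        assert (sen + spe) / 2 >= 0.95
        assert np.all((s >= 0) & (s <= 1))

    def test_permuted_labels_chance_level(self, rng):
        """Random labels: mean held-out BAC near 0.5 over 20 repetitions."""
        n, d = 60, 5
        X = rng.normal(size=(n, d))
        Xte = rng.normal(size=(30, d))
        yte = np.array([0] * 15 + [1] * 15)
        bacs = []
        for _ in range(20):
            y = rng.permutation([0] * (n // 2) + [1] * (n // 2))
            s = fit_predict_feature_set(_df(X), y, _df(Xte), FAST)
            pred = (s >= 0.5).astype(int)
            sen = np.mean(pred[yte == 1])
            spe = np.mean(1 - pred[yte == 0])
            bacs.append((sen + spe) / 2)
        assert 0.4 <= np.mean(bacs) <= 0.6

    def test_single_class_training_errors(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_predict_feature_set(_df(X), np.zeros(10, int), _df(X[:2]), FAST)

    def test_prediction_independence_across_test_rows(self, rng):
        """Dropping one test subject leaves the others' scores unchanged."""
        n, d = 24, 4
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, d))
        X[y == 1] += 1.0
        Xte = rng.normal(size=(5, d))
        cfg = EnsembleConfig(seed=0, calibration_cv=5, classifiers=("logreg", "rforest"))
        s_all = fit_predict_feature_set(_df(X), y, _df(Xte), cfg)
        s_sub = fit_predict_feature_set(_df(X), y, _df(Xte[:-1]), cfg)
        np.testing.assert_allclose(s_all[:-1], s_sub, atol=1e-12)

    def test_reproducible_from_seed(self, rng):
        n, d = 20, 3
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, d))
        Xte = rng.normal(size=(4, d))
        cfg = EnsembleConfig(seed=3, calibration_cv=5)
        s1 = fit_predict_feature_set(_df(X), y, _df(Xte), cfg)
        s2 = fit_predict_feature_set(_df(X), y, _df(Xte), cfg)
        np.testing.assert_array_equal(s1, s2)


class TestLateFusion:
    def test_mean_positive(self):
        score, cls = late_fuse({"a": 0.9, "b": 0.7, "c": 0.8})
        assert score == pytest.approx(0.8)
        assert cls == 1

    def test_single_set_identity(self):
        score, cls = late_fuse({"a": 0.3})
        assert score == 0.3
        assert cls == 0

    def test_boundary_positive(self):
        score, cls = late_fuse({"a": 0.4, "b": 0.6})
        assert score == pytest.approx(0.5)
        assert cls == 1

    def test_missing_sets_skipped(self):
        score, _ = late_fuse({"a": 0.8, "b": None, "c": np.nan})
        assert score == 0.8

    def test_no_sets_errors(self):
        with pytest.raises(ValueError):
            late_fuse({"a": None})

    def test_majority_mode(self):
        score, cls = late_fuse({"a": 0.9, "b": 0.6, "c": 0.1}, mode="majority")
        assert score == pytest.approx(2 / 3)
        assert cls == 1

    def test_multiclass_tie_break_order(self):
        assert fuse_multiclass({"SCZ": 0.4, "MDD": 0.4, "HC": 0.2}) == "SCZ"
        assert fuse_multiclass({"SCZ": 0.1, "MDD": 0.4, "HC": 0.4}) == "MDD"
        assert fuse_multiclass({"SCZ": 0.1, "MDD": 0.2, "HC": 0.9}) == "HC"


def test_fused_bac_not_far_below_best_single_modality():
    """With signal in both modalities, fusion loses at most 0.05 BAC."""
    from avphenotype import CohortConfig, generate_cohort

    cfg_ens = EnsembleConfig(seed=0, calibration_cv=5, classifiers=("logreg",))
    deltas = []
    for seed in range(5):
        cfg = CohortConfig(
            n_scz=12, n_mdd=0, n_hc=12, sessions=1, effect_size=1.2,
            feature_sets=("LIWC", "Diction"),
            table_dims={"LIWC": 16, "Diction": 12}, seed=seed,
        )
        b = generate_cohort(cfg)
        rec = b.records_for("baseline")
        y = (rec.diagnosis == "SCZ").astype(int).to_numpy()
        per_set = {}
        for fs in ("LIWC", "Diction"):
            scores = np.empty(len(rec))
            for i, rid in enumerate(rec.index):
                tr_ids = [r for r in rec.index if r != rid]
                scores[i] = fit_predict_feature_set(
                    b.tables[fs].loc[tr_ids], y[rec.index != rid],
                    b.tables[fs].loc[[rid]], cfg_ens,
                )[0]
            per_set[fs] = scores

        def bac(scores):
            pred = (scores >= 0.5).astype(int)
            return (np.mean(pred[y == 1]) + np.mean(1 - pred[y == 0])) / 2

        fused = bac((per_set["LIWC"] + per_set["Diction"]) / 2)
        best = max(bac(per_set["LIWC"]), bac(per_set["Diction"]))
        deltas.append(fused - best)
    assert np.mean(deltas) >= -0.05
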