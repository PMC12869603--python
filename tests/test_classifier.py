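"""Responder labelling, nested LOOCV, permutation significance, importances."""

import numpy as np
import pandas as pd
import pytest

import fpconn as fp
from fpconn.classify import ModelSpec
from fpconn.connectome import FPConnError


def _clinical(rows):
    return pd.DataFrame(rows, columns=["subject_id", "updrs_bl", "updrs_fu"])


class TestLabelResponders:
    @pytest.mark.parametrize("bl,fu,expected_delta,expected_resp", [
        (40.0, 34.0, 15.0, True),       # boundary is inclusive
        (40.0, 40.0, 0.0, False),
        (37.8, 32.5, 14.021, False),    # group-mean improvement < 15%
    ])
    def test_delta_and_threshold(self, bl, fu, expected_delta, expected_resp):
        out = fp.label_responders(_clinical([("s1", bl, fu)]))
        assert out["delta_percent"].iloc[0] == pytest.approx(expected_delta,
                                                             abs=1e-3)
        assert bool(out["responder"].iloc[0]) is expected_resp

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(FPConnError, match="s2"):
            fp.label_responders(_clinical([("s1", 30, 20), ("s2", 0, 5)]))

    def test_threshold_monotone(self):
        rng = np.random.default_rng(0)
        rows = [(f"s{k}", b, f) for k, (b, f) in enumerate(
            zip(rng.uniform(20, 60, 30), rng.uniform(15, 60, 30)))]
        counts = [fp.label_responders(_clinical(rows), t)["responder"].sum()
                  for t in (5, 10, 15, 20, 30)]
        assert np.all(np.diff(counts) <= 0)


def _features(x, ids=None):
    ids = ids or [f"s{k}" for k in range(len(x))]
    cols = [f"f{k}" for k in range(x.shape[1])]
    return pd.DataFrame(x, index=ids, columns=cols)


_FAST_KNN = ModelSpec("k_nearest_neighbors",
                      grid={"clf__n_neighbors": [3]}, seed=0)


class TestNestedLOOCV:
    def test_separable_classes_are_perfect(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(8, 1, (11, 4))])
        y = pd.Series([0] * 12 + [1] * 11, index=_features(x).index)
        spec = ModelSpec("k_nearest_neighbors",
                         grid={"clf__n_neighbors": [3, 5]}, seed=0)
        rep = fp.nested_loocv_classify(_features(x), y, spec)
        assert rep.metrics["accuracy"] == 1.0
        assert rep.metrics["roc_auc"] == 1.0

    def test_each_subject_held_out_exactly_once(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 3))
        feats = _features(x)
        y = pd.Series([0, 1] * 5, index=feats.index)
        rep = fp.nested_loocv_classify(feats, y, _FAST_KNN)
        assert sorted(rep.per_fold_predictions["subject_id"]) == \
            sorted(feats.index)
        assert len(rep.per_fold_predictions) == 10

    def test_shuffled_labels_score_near_majority_rate(self):
        rng = np.random.default_rng(3)
        accs = []
        for seed in range(10):
            x = rng.standard_normal((20, 5))
            feats = _features(x)
            y = pd.Series(rng.permutation([0] * 8 + [1] * 12),
                          index=feats.index)
            rep = fp.nested_loocv_classify(feats, y, _FAST_KNN)
            accs.append(rep.metrics["accuracy"])
        assert abs(np.mean(accs) - 0.6) < 0.2

    def test_standardization_is_fit_on_training_only(self):
        """An implementation that leaks the held-out subject into the
        scaler behaves differently on a crafted dataset with one extreme
        outlier."""
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.preprocessing import StandardScaler

        # one extreme outlier in the second feature: including the held-out
        # subject in the scaler rescales the distance metric
        rng = np.random.default_rng(0)
        x = np.column_stack([rng.normal(0, 1, 8), rng.normal(0, 1, 8)])
        x[0, 1] = rng.uniform(20, 60)
        y_arr = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        rng.shuffle(y_arr)
        feats = _features(x)
        y = pd.Series(y_arr, index=feats.index)
        rep = fp.nested_loocv_classify(feats, y, _FAST_KNN)
        # leaky variant: scaler fit on ALL subjects including the test one
        leaky = []
        for i in range(len(x)):
            train = np.delete(np.arange(len(x)), i)
            scaler = StandardScaler().fit(x)  # the leak
            clf = KNeighborsClassifier(n_neighbors=3).fit(
                scaler.transform(x[train]), y.iloc[train])
            leaky.append(int(clf.predict(scaler.transform(x[i:i + 1]))[0]))
        assert list(rep.per_fold_predictions["pred"]) != leaky

    def test_single_class_rejected(self):
        x = np.random.default_rng(4).standard_normal((8, 2))
        feats = _features(x)
        with pytest.raises(FPConnError):
            fp.nested_loocv_classify(feats, pd.Series(np.zeros(8, dtype=int),
                                                      index=feats.index),
                                     _FAST_KNN)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((14, 4))
        feats = _features(x)
        y = pd.Series([0, 1] * 7, index=feats.index)
        spec = ModelSpec("random_forest",
                         grid={"clf__n_estimators": [50],
                               "clf__max_depth": [None, 2]}, seed=7)
        r1 = fp.nested_loocv_classify(feats, y, spec)
        r2 = fp.nested_loocv_classify(feats, y, spec)
        assert r1.metrics == r2.metrics


class TestCoupledOutcome:
    def test_planted_outcome_is_predictable(self, coupled_cohort,
                                            coupled_features):
        """Topology of the planted discriminative subnetwork predicts
        responder status well above chance."""
        labels = fp.label_responders(
            coupled_cohort["clinical"]).set_index("subject_id")["responder"]
        spec = ModelSpec("random_forest",
                         grid={"clf__n_estimators": [100],
                               "clf__max_depth": [None, 3]}, seed=0)
        rep = fp.nested_loocv_classify(
            coupled_features["control_gt_patient"], labels, spec)
        assert rep.metrics["roc_auc"] > 0.7

    def test_uncoupled_mask_is_at_chance(self, coupled_cohort,
                                         coupled_features):
        """Features from the mask planted in the opposite direction carry no
        outcome signal."""
        labels = fp.label_responders(
            coupled_cohort["clinical"]).set_index("subject_id")["responder"]
        sig = fp.permutation_significance(
            coupled_features["patient_gt_control"], labels, _FAST_KNN,
            n_perm=99, seed=0)
        assert all(p > 0.05 for p in sig.p_adj.values())

    def test_permutation_significance_detects_coupling(self, coupled_cohort,
                                                       coupled_features):
        labels = fp.label_responders(
            coupled_cohort["clinical"]).set_index("subject_id")["responder"]
        spec = ModelSpec("logistic_regression", grid={"clf__C": [1.0]},
                         seed=0)
        sig = fp.permutation_significance(
            coupled_features["control_gt_patient"], labels, spec,
            n_perm=199, seed=0)
        assert sig.p_adj["accuracy"] < 0.05
        assert sig.p_adj["roc_auc"] < 0.05


class TestPermutationCalibration:
    def test_null_p_values_rarely_significant(self):
        """With features independent of labels, adjusted p-values exceed
        0.05 in nearly all repetitions."""
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            x = rng.standard_normal((16, 4))
            feats = _features(x)
            y = pd.Series(rng.permutation([0] * 7 + [1] * 9),
                          index=feats.index)
            sig = fp.permutation_significance(feats, y, _FAST_KNN,
                                              n_perm=60, seed=rep)
            hits += any(p < 0.05 for p in sig.p_adj.values())
        assert hits <= 1

    def test_weak_observed_metric_gives_large_p(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((16, 3))
        feats = _features(x)
        y = pd.Series([0, 1] * 8, index=feats.index)
        sig = fp.permutation_significance(feats, y, _FAST_KNN, n_perm=60,
                                          seed=1)
        # at least one metric below its null median under the null
        assert max(sig.p_raw.values()) > 0.5


class TestImportances:
    def test_planted_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        n = 24
        y_arr = np.array([0, 1] * (n // 2))
        x = rng.standard_normal((n, 8))
        x[:, 4] += 3.0 * y_arr
        feats = _features(x)
        y = pd.Series(y_arr, index=feats.index)
        # every split sees all features so the separating one is always
        # preferred; MDI then concentrates on it
        spec = ModelSpec("random_forest",
                         grid={"clf__n_estimators": [100],
                               "clf__max_features": [None]}, seed=0)
        rep = fp.nested_loocv_classify(feats, y, spec)
        shares = fp.feature_importance_summary(rep)
        assert shares.index[0] == "f4"
        assert shares.iloc[0] > 0.5
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_noise_features_share_importance_evenly(self):
        rng = np.random.default_rng(9)
        shares = []
        for seed in range(3):
            x = rng.standard_normal((24, 8))
            feats = _features(x)
            y = pd.Series([0, 1] * 12, index=feats.index)
            spec = ModelSpec("random_forest",
                             grid={"clf__n_estimators": [100]}, seed=seed)
            rep = fp.nested_loocv_classify(feats, y, spec)
            shares.append(fp.feature_importance_summary(rep).sort_index())
        mean_share = pd.concat(shares, axis=1).mean(axis=1)
        assert mean_share.max() - mean_share.min() < 0.2

    def test_non_tree_family_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((10, 3))
        feats = _features(x)
        y = pd.Series([0, 1] * 5, index=feats.index)
        spec = ModelSpec("k_nearest_neighbors",
                         grid={"clf__n_neighbors": [3]}, seed=0)
        rep = fp.nested_loocv_classify(feats, y, spec)
        with pytest.raises(FPConnError, match="importance undefined"):
            fp.feature_importance_summary(rep)
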