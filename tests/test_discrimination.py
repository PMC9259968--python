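"""ROC / AUC, leave-one-out SVM, permutation null."""

import numpy as np
import pytest
from sklearn.svm import SVC

import peraf
from peraf import FeatureTable, ValidationError
from peraf.discrimination import mann_whitney_auc, roc_points


def table(features, labels, subjects=None, regions=None):
    features = np.atleast_2d(np.asarray(features, float))
    if features.shape[0] == 1:
        features = features.T
    n = features.shape[0]
    return FeatureTable(
        subjects=subjects or [f"s{i:02d}" for i in range(n)],
        labels=labels, features=features,
        region_names=regions or [f"r{j}" for j in range(features.shape[1])])


class TestRegionalMeans:
    def _maps(self, arrays):
        return [peraf.AmplitudeMap(data=a, affine=np.eye(4), metric="PerAF",
                                   mask=np.ones(a.shape, bool))
                for a in arrays]

    def test_values(self):
        labels_vol = np.zeros((4, 4, 4), int)
        labels_vol[0, 0, 0] = 1                      # single voxel
        labels_vol[2, 2, 0:3] = 2                    # three voxels
        a = np.zeros((4, 4, 4))
        a[0, 0, 0] = 7.5
        a[2, 2, 0:3] = [1.0, 2.0, 6.0]
        b = np.full((4, 4, 4), 5.0)
        ft = peraf.extract_regional_means(self._maps([a, b]), labels_vol,
                                          ["p1", "c1"], ["patient", "control"])
        np.testing.assert_allclose(ft.features, [[7.5, 3.0], [5.0, 5.0]])

    def test_empty_region_rejected(self):
        labels_vol = np.zeros((3, 3, 3), int)
        with pytest.raises(ValidationError):
            peraf.extract_regional_means(self._maps([np.ones((3, 3, 3))] * 2),
                                         labels_vol, ["a", "b"],
                                         ["patient", "control"])


class TestRoc:
    def test_perfect_separation_auc_one(self):
        r = peraf.roc_analysis(np.array([1, 2, 3, 8, 9, 10.0]),
                               ["control"] * 3 + ["patient"] * 3)
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_worked_example_three_of_four_pairs(self):
        # patients {2, 4}, controls {1, 3}: 3 of 4 pairs concordant
        r = peraf.roc_analysis(np.array([2.0, 4.0, 1.0, 3.0]),
                               ["patient", "patient", "control", "control"])
        assert r.auc == 0.75
        assert r.direction == "higher_in_patients"

    def test_orientation_flips_for_decreased_marker(self):
        # marker lower in patients (the planted direction)
        r = peraf.roc_analysis(np.array([1.0, 2.0, 8.0, 9.0]),
                               ["patient", "patient", "control", "control"])
        assert r.auc == 1.0 and r.direction == "lower_in_patients"

    def test_auc_equals_mann_whitney_with_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(6, 25))
            y = np.zeros(n, int)
            y[rng.permutation(n)[:int(rng.integers(2, n - 2))]] = 1
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            fpr, tpr, _ = roc_points(scores, y)
            trap = float(np.trapezoid(tpr, fpr))
            assert abs(trap - mann_whitney_auc(scores, y)) < 1e-12

    def test_delong_ci_matches_pROC_oracle(self):
        # frozen from R pROC ci.auc(method="delong") on the same data
        pat = [1.5047170798, 0.1600158938, 1.9504511958, 2.1405647164,
               -0.7510351887, -0.1021795069, 1.3278404032, 0.8837574077,
               1.1831988425, 0.3469560724, 2.0793979749, 1.9777919354]
        con = [0.0660306976, 1.1272412070, 0.4675093423, -0.8592924629,
               0.3687507841, -0.9588826008, 0.8784503013, -0.0499259110,
               -0.1848623635, -0.6809295444, 1.2225413387, -0.1545294821,
               -0.4283278222, -0.3521335505]
        r = peraf.roc_analysis(np.array(pat + con),
                               ["patient"] * 12 + ["control"] * 14)
        assert r.auc == pytest.approx(0.809523809524, abs=1e-10)
        assert r.ci95[0] == pytest.approx(0.632566405096, abs=1e-9)
        assert r.ci95[1] == pytest.approx(0.986481213952, abs=1e-9)

    def test_ci_brackets_auc_within_unit_interval(self, rng):
        scores = rng.normal(0, 1, 20)
        r = peraf.roc_analysis(scores, ["patient"] * 10 + ["control"] * 10)
        assert 0.0 <= r.ci95[0] <= r.auc <= r.ci95[1] <= 1.0

    def test_permuted_labels_average_to_half(self, rng):
        aucs = []
        scores = rng.normal(0, 1, 20)
        base = np.array([1] * 10 + [0] * 10)
        for _ in range(500):
            y = rng.permutation(base)
            aucs.append(mann_whitney_auc(scores, y))
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-3

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            peraf.roc_analysis(np.arange(4.0), ["patient"] * 4)

    def test_constant_feature_degenerates_to_half(self):
        with pytest.warns(UserWarning, match="constant"):
            r = peraf.roc_analysis(np.full(8, 2.0),
                                   ["patient"] * 4 + ["control"] * 4)
        assert r.auc == 0.5


class TestLooSvm:
    def test_separable_features_classified_perfectly(self, rng):
        feats = np.r_[rng.normal(0, 0.2, 10), rng.normal(6, 0.2, 10)]
        t = table(feats, ["control"] * 10 + ["patient"] * 10)
        res = peraf.loo_svm(t)
        assert res.accuracy == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.auc_decision == 1.0

    def test_metrics_recompute_from_confusion_counts(self, rng):
        feats = rng.normal(0, 1, 36)
        t = table(feats, ["patient"] * 18 + ["control"] * 18)
        res = peraf.loo_svm(t)
        c = res.confusion
        assert res.accuracy == (c["tp"] + c["tn"]) / res.n
        assert res.sensitivity == c["tp"] / (c["tp"] + c["fn"])
        assert res.specificity == c["tn"] / (c["tn"] + c["fp"])
        preds = np.array([p == "patient" for p in res.predictions], int)
        assert (preds == t.y).mean() == res.accuracy

    def test_shuffled_labels_near_chance(self, rng):
        feats = rng.normal(0, 1, (36, 2))
        y = rng.permutation([1] * 18 + [0] * 18)
        labels = ["patient" if v else "control" for v in y]
        res = peraf.loo_svm(table(feats, labels))
        # binomial 95% band around 0.5 at N=36 is roughly +-0.167
        assert 0.25 <= res.accuracy <= 0.75

    def test_fold_prediction_matches_manual_refit(self, rng):
        # no-leakage oracle: refit fold i by hand with training-only
        # z-scoring and compare the decision value
        feats = rng.normal(0, 1, (12, 2))
        labels = ["patient"] * 6 + ["control"] * 6
        t = table(feats, labels)
        res = peraf.loo_svm(t, c_param=1.0)
        y = t.y
        for i in (0, 5, 11):
            train = np.arange(12) != i
            mu, sd = feats[train].mean(0), feats[train].std(0)
            clf = SVC(kernel="linear", C=1.0)
            clf.fit((feats[train] - mu) / sd, y[train])
            dec = clf.decision_function(((feats[i] - mu) / sd)[None, :])[0]
            assert res.decision_values[i] == pytest.approx(dec, abs=1e-12)

    def test_heldout_value_cannot_influence_its_own_scaler(self, rng):
        feats = rng.normal(0, 1, (10, 1))
        feats[:5] += 3.0
        labels = ["patient"] * 5 + ["control"] * 5
        base = peraf.loo_svm(table(feats.copy(), labels))
        bumped = feats.copy()
        bumped[7, 0] += 100.0  # only subject 7's own feature changes
        res = peraf.loo_svm(table(bumped, labels))
        # folds holding out other subjects see a changed training set, but
        # subject 7's own fold trains on identical data: its decision value
        # must move only through the (z-scored) test point itself
        mu = np.delete(feats, 7, axis=0).mean()
        sd = np.delete(feats, 7, axis=0).std()
        clf = SVC(kernel="linear", C=1.0)
        y = np.array([1] * 5 + [0] * 5)
        clf.fit(((np.delete(feats, 7, axis=0) - mu) / sd), np.delete(y, 7))
        expected = clf.decision_function([[(bumped[7, 0] - mu) / sd]])[0]
        assert res.decision_values[7] == pytest.approx(expected, abs=1e-12)
        assert base.decision_values[7] != res.decision_values[7]

    def test_overlapping_gaussians_track_bayes_rate(self, rng):
        # classes N(-d, 1) and N(+d, 1) with d chosen so the Bayes
        # accuracy is Phi(d) = 0.75
        from scipy.stats import norm
        d = norm.ppf(0.75)
        feats = np.r_[rng.normal(-d, 1, 18), rng.normal(d, 1, 18)]
        t = table(feats, ["control"] * 18 + ["patient"] * 18)
        res = peraf.loo_svm(t)
        assert abs(res.accuracy - 0.75) <= 0.10

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            peraf.loo_svm(table([1.0, 2.0], ["patient", "control"]))


class TestPermutationTest:
    def test_separated_features_reach_smallest_p(self, rng):
        feats = np.r_[rng.normal(0, 0.1, 8), rng.normal(5, 0.1, 8)]
        t = table(feats, ["patient"] * 8 + ["control"] * 8)
        res = peraf.permutation_test(t, n_permutations=1000, seed=5)
        assert res.p_value == pytest.approx(1.0 / 1001.0)
        assert res.observed_accuracy == 1.0

    def test_observed_below_null_median_gives_large_p(self):
        # uninformative 1-D features on which LOO anti-predicts: the
        # observed accuracy falls below the null median, so rank logic
        # forces a large p
        feats = np.random.default_rng(0).normal(0, 1, (12, 1))
        t = table(feats, ["patient"] * 6 + ["control"] * 6)
        obs = peraf.loo_svm(t).accuracy
        res = peraf.permutation_test(t, n_permutations=150, seed=100)
        assert obs < res.null_quantiles["q50"]
        assert res.p_value > 0.5

    def test_deterministic_given_seed(self, rng):
        feats = rng.normal(0, 1, 12)
        t = table(feats, ["patient"] * 6 + ["control"] * 6)
        a = peraf.permutation_test(t, n_permutations=150, seed=9)
        b = peraf.permutation_test(t, n_permutations=150, seed=9)
        assert a.p_value == b.p_value

    def test_zero_permutations_rejected(self, rng):
        t = table(rng.normal(0, 1, 8), ["patient"] * 4 + ["control"] * 4)
        with pytest.raises(ValidationError):
            peraf.permutation_test(t, n_permutations=0)

    def test_low_resolution_warns(self, rng):
        t = table(rng.normal(0, 1, 8), ["patient"] * 4 + ["control"] * 4)
        with pytest.warns(UserWarning, match="resolution"):
            peraf.permutation_test(t, n_permutations=50, seed=2)


class TestFeatureTableIO:
    def test_roundtrip(self, tmp_path, rng):
        t = table(rng.normal(1, 0.1, (6, 2)),
                  ["patient"] * 3 + ["control"] * 3, regions=["rdsfg", "rpcg"])
        p = t.save(tmp_path / "features.tsv")
        back = FeatureTable.load(p)
        assert back.labels == t.labels and back.region_names == t.region_names
        np.testing.assert_allclose(back.features, t.features, rtol=1e-9)

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            table([np.nan, 1.0, 2.0, 3.0], ["patient", "patient",
                                            "control", "control"])
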