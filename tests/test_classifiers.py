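import numpy as np
import pytest
from scipy.integrate import quad

from mci_harmonix.classifiers import (
    ClassifierSpec,
    KernelNaiveBayes,
    KNNClassifier,
    LogisticLasso,
    RUSBoostClassifier,
    apply_cost_matrix,
    hyperparameter_space,
    kernel_density,
    make_classifier,
    predict_scores,
)


class TestKernelDensity:
    def test_single_point_box_closed_form(self):
        # (1/(1*2)) * K(0) with box K(0) = 1/2
        assert kernel_density([1.0], "box", 2.0, 1.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("kernel", ["box", "epanechnikov", "normal", "triangle"])
    def test_density_integrates_to_one(self, kernel, rng):
        train = rng.normal(0, 1, 15)
        total, _ = quad(
            lambda x: kernel_density(train, kernel, 0.7, x), -15, 15, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_normal_kernel_matches_gaussian_sum(self, rng):
        train = rng.normal(0, 2, 20)
        w = 0.5
        queries = rng.uniform(-3, 3, 5)
        for q in queries:
            expected = np.mean(
                np.exp(-0.5 * ((q - train) / w) ** 2) / (w * np.sqrt(2 * np.pi))
            )
            assert kernel_density(train, "normal", w, q) == pytest.approx(expected)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            kernel_density([0.0], "box", 0.0, 0.0)


class TestKernelNaiveBayes:
    def test_separated_gaussians_perfect_training_accuracy(self, rng):
        X = np.concatenate([rng.normal(0, 1, 100), rng.normal(10, 1, 100)])[:, None]
        y = np.array(["HC"] * 100 + ["uHC"] * 100)
        nb = KernelNaiveBayes("normal").fit(X, y)
        assert (nb.predict(X) == y).mean() == 1.0

    def test_kernel_mode_beats_gaussian_on_bimodal_class(self, rng):
        # interleaved bimodal classes: the single-Gaussian class models are
        # nearly identical, so Gaussian NB collapses while a KDE separates
        n = 150
        hc = np.concatenate([rng.normal(-3, 0.4, n // 2), rng.normal(3, 0.4, n // 2)])
        uhc = np.concatenate([rng.normal(0, 0.4, n // 2), rng.normal(6, 0.4, n // 2)])
        X = np.concatenate([hc, uhc])[:, None]
        y = np.array(["HC"] * n + ["uHC"] * n)
        acc_normal = (KernelNaiveBayes("normal").fit(X, y).predict(X) == y).mean()
        acc_kernel = (KernelNaiveBayes("kernel").fit(X, y).predict(X) == y).mean()
        assert acc_kernel - acc_normal > 0.10

    def test_decision_boundary_at_midpoint_for_symmetric_classes(self, rng):
        # equal priors, equal variances: the Bayes boundary is (mu0+mu1)/2
        X = np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])[:, None]
        y = np.array(["HC"] * 500 + ["uHC"] * 500)
        nb = KernelNaiveBayes("normal").fit(X, y)
        mu0, mu1 = nb.theta_["HC"][0], nb.theta_["uHC"][0]
        boundary = (mu0 + mu1) / 2
        eps = 0.05
        assert nb.predict([[boundary - eps]])[0] == "HC"
        assert nb.predict([[boundary + eps]])[0] == "uHC"

    def test_cost_shifts_posterior_odds_threshold_analytically(self, rng):
        # with weight delta on uHC, predict uHC iff P(uHC|x)/P(HC|x) > 1/delta
        X = np.concatenate([rng.normal(0, 1, 200), rng.normal(3, 1, 200)])[:, None]
        y = np.array(["HC"] * 200 + ["uHC"] * 200)
        delta = 5.0
        base = KernelNaiveBayes("normal").fit(X, y)
        weighted = KernelNaiveBayes("normal", class_weight={"uHC": delta, "HC": 1.0}).fit(X, y)
        grid = np.linspace(-2, 5, 400)[:, None]
        proba = base.predict_proba(grid)
        odds = proba[:, 1] / proba[:, 0]
        expected = np.where(odds > 1.0 / delta, "uHC", "HC")
        np.testing.assert_array_equal(weighted.predict(grid), expected)

    def test_kernel_nb_converges_to_gaussian_nb_on_gaussian_data(self, rng):
        n = 2000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(1.5, 1, n)])[:, None]
        y = np.array(["HC"] * n + ["uHC"] * n)
        pred_g = KernelNaiveBayes("normal").fit(X, y).predict(X)
        pred_k = KernelNaiveBayes("kernel", kernel="normal").fit(X, y).predict(X)
        assert (pred_g == pred_k).mean() >= 0.95

    def test_row_order_permutation_invariance(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array(["HC"] * 30 + ["uHC"] * 30)
        perm = rng.permutation(60)
        p1 = KernelNaiveBayes("normal").fit(X, y).predict(X)
        p2 = KernelNaiveBayes("normal").fit(X[perm], y[perm]).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestBackedFamilies:
    def test_knn_k1_memorizes_training_data(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array(["HC"] * 20 + ["uHC"] * 20)
        knn = KNNClassifier(n_neighbors=1).fit(X, y)
        assert (knn.predict(X) == y).mean() == 1.0

    def test_linear_svm_separable_zero_training_errors(self, rng):
        X = np.vstack([rng.normal((-3, -3), 0.5, (30, 2)), rng.normal((3, 3), 0.5, (30, 2))])
        y = np.array(["HC"] * 30 + ["uHC"] * 30)
        spec = ClassifierSpec("svm")
        m = make_classifier(spec, {"kernel": "linear", "kernel_scale": 1.0,
                                   "box_constraint": 10.0})
        m.fit(X, y)
        assert (m.predict(X) == y).mean() == 1.0

    def test_logistic_heavy_penalty_shrinks_all_slopes_to_zero(self, rng):
        X = rng.normal(size=(100, 5))  # standardized noise features
        y = np.array(["HC"] * 50 + ["uHC"] * 50)
        clf = LogisticLasso(lam=10.0).fit(X, y)
        np.testing.assert_array_equal(clf.coef_, 0.0)

    @pytest.mark.parametrize(
        "metric",
        ["cityblock", "chebychev", "correlation", "cosine", "euclidean", "hamming",
         "jaccard", "mahalanobis", "minkowski", "seuclidean", "spearman"],
    )
    def test_all_knn_metrics_fit_and_predict(self, metric, rng):
        X = rng.normal(size=(40, 4)) + np.array([0, 0, 0, 0])
        X[20:] += 2.0
        y = np.array(["HC"] * 20 + ["uHC"] * 20)
        knn = KNNClassifier(n_neighbors=5, metric=metric).fit(X, y)
        pred = knn.predict(X)
        assert set(pred) <= {"HC", "uHC"}
        assert (pred == y).mean() > 0.6  # shifted classes remain separable

    def test_out_of_space_hyperparameters_rejected_with_bound(self):
        with pytest.raises(ValueError, match=r"\[5, 30\]"):
            make_classifier(ClassifierSpec("knn"), {"n_neighbors": 2})
        with pytest.raises(ValueError, match="lam"):
            make_classifier(ClassifierSpec("logistic"), {"lam": 100.0})
        with pytest.raises(ValueError, match="categories|not in"):
            make_classifier(ClassifierSpec("svm"), {"kernel": "sigmoid"})

    def test_gaussian_and_rbf_svm_are_aliases(self, small_balanced_cohort):
        from mci_harmonix.schema import EFFECT_REGIONS

        X = small_balanced_cohort[EFFECT_REGIONS].to_numpy()
        y = small_balanced_cohort["group"].to_numpy().astype(str)
        spec = ClassifierSpec("svm")
        hp = {"kernel_scale": 1.0, "box_constraint": 1.0}
        p1 = make_classifier(spec, {"kernel": "gaussian", **hp}).fit(X, y).predict(X)
        p2 = make_classifier(spec, {"kernel": "rbf", **hp}).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_score_transform_never_changes_labels(self, rng):
        X = rng.normal(size=(80, 3))
        X[40:] += 1.0
        y = np.array(["HC"] * 40 + ["uHC"] * 40)
        preds = {}
        for st_name in ("none", "logit", "invlogit", "doublelogit"):
            clf = LogisticLasso(lam=0.01, score_transform=st_name).fit(X, y)
            preds[st_name] = clf.predict(X)
        for st_name in ("logit", "invlogit", "doublelogit"):
            np.testing.assert_array_equal(preds["none"], preds[st_name])


class TestRUSBoost:
    def test_fits_and_separates(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(4, 1, (20, 2))])
        y = np.array(["HC"] * 100 + ["uHC"] * 20)
        rb = RUSBoostClassifier(n_estimators=30, random_state=0).fit(X, y)
        assert (rb.predict(X) == y).mean() > 0.9

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 3))
        X[40:] += 1.5
        y = np.array(["HC"] * 40 + ["uHC"] * 20)
        p1 = RUSBoostClassifier(n_estimators=20, random_state=5).fit(X, y).predict(X)
        p2 = RUSBoostClassifier(n_estimators=20, random_state=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_never_receives_delta(self):
        spec = ClassifierSpec("rusboost")
        out = apply_cost_matrix(spec, 7.0)
        assert out.delta == 1.0

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            RUSBoostClassifier(learning_rate=1.5).fit(np.zeros((4, 1)),
                                                      np.array(["a", "a", "b", "b"]))


class TestCostMatrix:
    def test_delta_one_is_identity(self):
        spec = ClassifierSpec("naive_bayes")
        out = apply_cost_matrix(spec, 1.0)
        assert out.delta == 1.0
        m = make_classifier(out)
        assert m.class_weight is None

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            apply_cost_matrix(ClassifierSpec("svm"), 0.0)

    def test_delta_increases_minority_tpr_at_heavy_imbalance(self, rng):
        # 10:1 imbalance with overlapping classes; delta = 10 must recover
        # strictly more converters than the cost-neutral rule
        n_maj, n_min = 300, 30
        X = np.concatenate([rng.normal(0, 1, n_maj), rng.normal(1.5, 1, n_min)])[:, None]
        y = np.array(["HC"] * n_maj + ["uHC"] * n_min)
        base = KernelNaiveBayes("normal").fit(X, y)
        weighted = KernelNaiveBayes("normal", class_weight={"uHC": 10.0, "HC": 1.0}).fit(X, y)
        tpr = lambda pred: (pred[y == "uHC"] == "uHC").mean()
        assert tpr(weighted.predict(X)) > tpr(base.predict(X))


class TestSpacesAndScores:
    def test_every_family_declares_a_space(self):
        for family in ("naive_bayes", "knn", "svm", "logistic", "rusboost"):
            space = hyperparameter_space(family)
            assert space, family
            for p in space:
                assert p["kind"] in ("real", "integer", "categorical")

    def test_predict_scores_orientation(self, rng):
        # scores must rank converters above controls for a separable problem
        from mci_harmonix.metrics import aroc

        X = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])[:, None]
        y = np.array(["HC"] * 50 + ["uHC"] * 50)
        for family, hp in [
            ("naive_bayes", {"distribution": "normal"}),
            ("logistic", {"lam": 0.01}),
            ("svm", {"kernel": "linear", "kernel_scale": 1.0, "box_constraint": 1.0}),
            ("rusboost", {"n_estimators": 20, "learning_rate": 0.5, "max_splits": 2}),
        ]:
            m = make_classifier(ClassifierSpec(family), hp, seed=0)
            m.fit(X, y)
            assert aroc(predict_scores(m, X), y) > 0.95, family
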