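import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mci_harmonix.ranking import (
    ancova_score,
    anova_score,
    average_percentages,
    bonferroni_adjust,
    build_subsets,
    chi2_score,
    kruskal_score,
    rank_features,
    relieff_score,
    to_percentages,
)


def _two_groups(rng, n=50, shift=0.0):
    values = np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)])
    labels = np.array(["HC"] * n + ["uHC"] * n)
    return values, labels


class TestAnova:
    def test_constant_feature_scores_zero(self):
        v = np.ones(20)
        labels = np.array(["HC"] * 10 + ["uHC"] * 10)
        F, p, s = anova_score(v, labels)
        assert (F, p, s) == (0.0, 1.0, 0.0)

    def test_strong_shift_highly_significant(self, rng):
        v, labels = _two_groups(rng, shift=2.0)
        _, p, s = anova_score(v, labels)
        assert p < 1e-6 and s == pytest.approx(-np.log(p))

    def test_f_equals_t_squared(self, rng):
        v, labels = _two_groups(rng, shift=0.5)
        F, p_f, _ = anova_score(v, labels)
        t, p_t = stats.ttest_ind(v[labels == "HC"], v[labels == "uHC"])
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)


class TestKruskal:
    def test_all_tied_scores_zero(self):
        v = np.full(12, 3.0)
        labels = np.array(["HC"] * 6 + ["uHC"] * 6)
        assert kruskal_score(v, labels) == (0.0, 1.0, 0.0)

    def test_monotone_transform_invariance(self, rng):
        v, labels = _two_groups(rng, n=20, shift=1.0)
        h1 = kruskal_score(v, labels)
        h2 = kruskal_score(np.exp(v), labels)
        assert h1 == pytest.approx(h2)

    def test_h_statistic_matches_hand_formula(self):
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        v = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array(["HC"] * 3 + ["uHC"] * 3)
        H, _, _ = kruskal_score(v, labels)
        ranks = stats.rankdata(v)
        N = 6
        expected = 12 / (N * (N + 1)) * sum(
            3 * (ranks[labels == g].mean() - (N + 1) / 2) ** 2 for g in ("HC", "uHC")
        )
        assert H == pytest.approx(expected)


class TestAncova:
    def _confounded(self, rng, n=150):
        labels = np.array(["HC"] * n + ["uHC"] * n)
        age = np.concatenate([rng.uniform(60, 80, n), rng.uniform(66, 86, n)])
        v = 5000 - 30 * age + rng.normal(0, 100, 2 * n)  # group acts only via age
        cov = pd.DataFrame({
            "age": age,
            "sex": rng.choice(["Male", "Female"], 2 * n),
            "education": rng.normal(16, 2, 2 * n),
            "icv": rng.normal(1.5e6, 1e5, 2 * n),
        })
        return v, labels, cov

    def test_covariate_absorbs_confounded_effect(self, rng):
        v, labels, cov = self._confounded(rng)
        _, p_ancova = ancova_score(v, labels, cov)
        _, p_anova, _ = anova_score(v, labels)
        assert p_ancova > 100 * p_anova

    def test_type_i_calibration_under_null(self):
        rejections = 0
        reps = 300
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            n = 100
            labels = np.array(["HC"] * n + ["uHC"] * n)
            v = rng.normal(0, 1, 2 * n)
            cov = pd.DataFrame({
                "age": rng.uniform(60, 86, 2 * n),
                "sex": rng.choice(["Male", "Female"], 2 * n),
                "education": rng.normal(16, 2, 2 * n),
                "icv": rng.normal(1.5e6, 1e5, 2 * n),
            })
            _, p = ancova_score(v, labels, cov)
            rejections += p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_orthogonal_covariates_leave_p_unchanged(self, rng):
        n = 200
        labels = np.array(["HC"] * n + ["uHC"] * n)
        v = np.concatenate([rng.normal(0, 1, n), rng.normal(0.4, 1, n)])
        cov = pd.DataFrame({
            "age": rng.uniform(60, 86, 2 * n),
            "icv": rng.normal(1.5e6, 1e5, 2 * n),
        })
        _, p_ancova = ancova_score(v, labels, cov)
        _, p_anova, _ = anova_score(v, labels)
        assert np.log(p_ancova) == pytest.approx(np.log(p_anova), abs=1.0)

    def test_collinear_covariates_named(self, rng):
        n = 40
        labels = np.array(["HC"] * n + ["uHC"] * n)
        age = rng.uniform(60, 86, 2 * n)
        cov = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(ValueError, match="age.*age2"):
            ancova_score(rng.normal(size=2 * n), labels, cov)


class TestChi2:
    def test_perfectly_separating_feature(self):
        v = np.concatenate([np.linspace(0, 1, 20), np.linspace(10, 11, 20)])
        labels = np.array(["HC"] * 20 + ["uHC"] * 20)
        chi2, p, _ = chi2_score(v, labels, n_bins=4)
        # oracle: disjoint supports give a pure 2x4 table -> chi2 = n exactly
        tbl = np.array([[10, 10, 0, 0], [0, 0, 10, 10]])
        chi2_ref, p_ref, _, _ = stats.chi2_contingency(tbl, correction=False)
        assert chi2 == pytest.approx(chi2_ref) and p == pytest.approx(p_ref)
        assert p < 1e-6

    def test_two_by_two_closed_form(self):
        # table (20,0; 0,20): chi2 = n = 40
        v = np.array([0.0] * 20 + [1.0] * 20)
        labels = np.array(["HC"] * 20 + ["uHC"] * 20)
        chi2, _, _ = chi2_score(v, labels, n_bins=2)
        assert chi2 == pytest.approx(40.0)

    def test_null_mean_score_near_one(self):
        # -ln(p) of a uniform p has mean 1
        scores = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            v = rng.normal(size=100)
            labels = np.array(["HC"] * 50 + ["uHC"] * 50)
            scores.append(chi2_score(v, labels)[2])
        assert 0.7 <= np.mean(scores) <= 1.3

    def test_requires_two_bins(self, rng):
        with pytest.raises(ValueError):
            chi2_score(rng.normal(size=10), np.array(["HC"] * 5 + ["uHC"] * 5), n_bins=1)


def _brute_force_relieff_k1(X, y):
    """Exhaustive oracle: all anchors, k=1 nearest hit/miss, Manhattan on
    range-scaled features, two equally sized classes."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    Xs = np.where(span > 0, X / np.where(span > 0, span, 1.0), 0.0)
    W = np.zeros(p)
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    for i in range(n):
        best_hit, best_miss = None, None
        for j in range(n):
            if j == i:
                continue
            d = np.abs(Xs[j] - Xs[i]).sum()
            if y[j] == y[i]:
                if best_hit is None or d < best_hit[0]:
                    best_hit = (d, j)
            else:
                if best_miss is None or d < best_miss[0]:
                    best_miss = (d, j)
        w_miss = priors[[c for c in classes if c != y[i]][0]] / (1 - priors[y[i]])
        W += -np.abs(Xs[best_hit[1]] - Xs[i]) + w_miss * np.abs(Xs[best_miss[1]] - Xs[i])
    return W / n


class TestReliefF:
    def test_constant_feature_weight_zero(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = np.array(["HC"] * 6 + ["uHC"] * 6)
        W = relieff_score(X, y, k_neighbors=2)
        assert W[0] == 0.0

    def test_separated_feature_beats_permutation_null(self):
        # sign test against the label-permutation null: the permutation
        # distribution of the weight is centered at zero, so the fully
        # separated labeling must sit far in its upper tail
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.uniform(0, 0.4, 15), rng.uniform(0.6, 1.0, 15)])[:, None]
        y = np.array(["HC"] * 15 + ["uHC"] * 15)
        observed = relieff_score(X, y, k_neighbors=1)[0]
        assert observed > 0
        null = [
            relieff_score(X, np.random.default_rng(s).permutation(y), k_neighbors=1)[0]
            for s in range(100)
        ]
        assert observed > np.quantile(null, 0.95)
        assert abs(np.median(null)) < observed / 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_six_samples(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(6, 2))
        y = np.array(["HC", "HC", "HC", "uHC", "uHC", "uHC"])
        np.testing.assert_allclose(
            relieff_score(X, y, k_neighbors=1), _brute_force_relieff_k1(X, y), atol=1e-12
        )

    def test_affine_feature_scaling_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array(["HC"] * 15 + ["uHC"] * 15)
        W1 = relieff_score(X, y, k_neighbors=3)
        X2 = X * np.array([10.0, 0.01, 5.0]) + np.array([3.0, -7.0, 100.0])
        W2 = relieff_score(X2, y, k_neighbors=3)
        np.testing.assert_allclose(W1, W2, atol=1e-12)


class TestPercentages:
    def test_single_positive_score_gets_100(self):
        np.testing.assert_allclose(to_percentages([0.5, -1.0, 0.0]), [100.0, 0.0, 0.0])

    def test_all_nonpositive_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = to_percentages([-1.0, 0.0])
        assert (out == 0).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=30))
    def test_positive_percentages_sum_to_100(self, raw):
        if not any(x > 0 for x in raw):
            return
        pct = to_percentages(raw)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert (pct >= 0).all()

    def test_average_is_mean_over_methods(self):
        P = np.array([[3.80, 6.07, 6.35, 13.50], [0.81, 0.25, 0.35, 0.0]])
        np.testing.assert_allclose(average_percentages(P), [7.43, 0.3525])


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni_adjust([0.001], 40)[0] == pytest.approx(0.04)
        assert bonferroni_adjust([0.5], 40)[0] == 1.0

    def test_vector_case_matches_elementwise_oracle(self, rng):
        p = rng.uniform(size=25)
        np.testing.assert_allclose(
            bonferroni_adjust(p), [min(1.0, 25 * x) for x in p]
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestSubsets:
    def test_identical_scores_put_everything_in_a(self, rng):
        n = 60
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["HC"] * 30 + ["uHC"] * 30,
            "sex": rng.choice(["Male", "Female"], n),
            "age": rng.uniform(60, 86, n),
            "education": rng.normal(16, 2, n),
            "mmse": rng.integers(25, 30, n),
            "icv": rng.normal(1.5e6, 1e5, n),
        })
        base = rng.normal(0, 1, n)
        for f in ("f1", "f2", "f3"):
            table[f] = base  # identical features -> identical scores
        scores = rank_features(table, features=["f1", "f2", "f3"], k_neighbors=2)
        subsets = build_subsets(scores)
        assert set(subsets.subset_a) == {"f1", "f2", "f3"}

    def test_c_is_subset_of_b(self, oasis_cohort):
        from mci_harmonix import PolynomialHarmonizer

        ht = PolynomialHarmonizer("residual").fit(oasis_cohort).transform(oasis_cohort)
        scores = rank_features(ht)
        subsets = build_subsets(scores)
        assert set(subsets.subset_c) <= set(subsets.subset_b)
        assert set(subsets.subset_c) <= set(subsets.subset_d)

    def test_scores_invariant_to_feature_order(self, adni_cohort):
        feats = ["Hippocampus", "entorhinal", "Amygdala", "cuneus"]
        s1 = rank_features(adni_cohort, features=feats)
        s2 = rank_features(adni_cohort, features=feats[::-1])
        for f in feats:
            assert s1.loc[f, "anova_score"] == pytest.approx(s2.loc[f, "anova_score"])
            assert s1.loc[f, "relieff_score"] == pytest.approx(s2.loc[f, "relieff_score"])
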