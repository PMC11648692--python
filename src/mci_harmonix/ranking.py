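"""Multi-criterion feature scoring and subset construction.

Each volumetric feature is scored by five criteria — one-way ANOVA,
Kruskal-Wallis, chi-square on a discretized copy, ReliefF, and a covariate-
adjusted ANCOVA — and the p-value based scores are expressed as -log(p)
(natural log by default). Because the raw scales differ, scores are converted
to percentages of the per-method positive-score total, and four feature
subsets are derived:

* A — features whose mean of the four method percentages is at or above the
  median of those means (ties included);
* B — features with strictly positive ReliefF weight;
* C — features selected by every contributing criterion simultaneously;
* D — features with Bonferroni-adjusted p <= 0.05 in ANOVA, ANCOVA and
  Kruskal-Wallis simultaneously.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "anova_score",
    "kruskal_score",
    "ancova_score",
    "chi2_score",
    "relieff_score",
    "to_percentages",
    "average_percentages",
    "bonferroni_adjust",
    "rank_features",
    "build_subsets",
    "FeatureSubsets",
]

SCORE_METHODS = ("chi2", "anova", "kruskal", "relieff")


def _neg_log(p: float, base: str = "e") -> float:
    p = max(float(p), np.finfo(float).tiny)
    return -np.log(p) if base == "e" else -np.log10(p)


def anova_score(values, labels, log_base: str = "e") -> tuple[float, float, float]:
    """One-way ANOVA of a feature on the two groups: (F, p, -log p)."""
    values = np.asarray(values, dtype=float)
    groups = [values[np.asarray(labels) == g] for g in pd.unique(np.asarray(labels))]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("anova_score requires two groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(values) == 0:
        return 0.0, 1.0, 0.0  # zero variance, equal means
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):
        return 0.0, 1.0, 0.0
    return float(F), float(p), _neg_log(p, log_base)


def kruskal_score(values, labels, log_base: str = "e") -> tuple[float, float, float]:
    """Kruskal-Wallis rank test with tie correction: (H, p, -log p)."""
    values = np.asarray(values, dtype=float)
    groups = [values[np.asarray(labels) == g] for g in pd.unique(np.asarray(labels))]
    if np.ptp(values) == 0:
        return 0.0, 1.0, 0.0  # all values tied
    H, p = stats.kruskal(*groups)
    return float(H), float(p), _neg_log(p, log_base)


def ancova_score(
    values,
    labels,
    covariates: pd.DataFrame,
) -> tuple[float, float]:
    """Partial F-test p for the group term in value ~ group + covariates.

    Covariates default to age, sex (binary coded), education and ICV in the
    pipeline driver. Returns (F_group, p_group).
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g = (labels == pd.unique(labels)[1]).astype(float)
    cov = covariates.copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "Male").astype(float)
    Z = cov.to_numpy(dtype=float)
    # collinearity screen among covariates
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(Z, rowvar=False)
    idx = np.triu_indices_from(corr, k=1)
    bad = np.where(np.abs(corr[idx]) > 1 - 1e-10)[0]
    if len(bad):
        i, j = idx[0][bad[0]], idx[1][bad[0]]
        raise ValueError(
            f"collinear covariates: {cov.columns[i]!r} and {cov.columns[j]!r}"
        )
    n = len(y)
    X_full = np.column_stack([np.ones(n), g, Z])
    X_red = np.column_stack([np.ones(n), Z])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")
    F = max(rss_red - rss_full, 0.0) / (rss_full / df_resid) if rss_full > 0 else np.inf
    p = float(stats.f.sf(F, 1, df_resid))
    return float(F), p


def chi2_score(
    values,
    labels,
    n_bins: int = 10,
    log_base: str = "e",
) -> tuple[float, float, float]:
    """Chi-square independence of (discretized feature) x group: (chi2, p, -log p).

    Continuous values are cut into ``n_bins`` equal-frequency bins on the
    pooled sample; bins empty in both groups are dropped (with the degrees of
    freedom adjusting automatically through the contingency shape).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if np.ptp(values) == 0:
        return 0.0, 1.0, 0.0
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)
    table = pd.crosstab(bins, labels).to_numpy()
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        return 0.0, 1.0, 0.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), _neg_log(p, log_base)


def relieff_score(
    X,
    y,
    k_neighbors: int = 10,
) -> np.ndarray:
    """ReliefF feature weights (Kononenko variant, all observations as anchors).

    For every anchor, the k nearest same-class neighbors (hits) and k nearest
    neighbors of the other class (misses) are found under the Manhattan
    distance on range-scaled features. Each feature's weight accumulates
    -mean(diff to hits) + P(miss class)/(1 - P(anchor class)) * mean(diff to
    misses), averaged over anchors, with diff(f, a, b) = |a_f - b_f| /
    (max_f - min_f). Constant features have diff defined as 0 and end with
    weight exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if any(counts < k_neighbors + 1):
        raise ValueError("relieff_score requires >= k+1 samples per class")
    if not np.all(np.isfinite(X)):
        raise ValueError("relieff_score: missing or non-finite values")
    rng_span = X.max(axis=0) - X.min(axis=0)
    ok = rng_span > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = X[:, ok] / rng_span[ok]  # constant features contribute diff 0

    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    # pairwise Manhattan distances on scaled features
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    W = np.zeros(p)
    for i in range(n):
        ci = y[i]
        hit_idx = np.where(y == ci)[0]
        hit_idx = hit_idx[hit_idx != i]
        k_h = min(k_neighbors, len(hit_idx))
        hits = hit_idx[np.argsort(D[i, hit_idx], kind="stable")[:k_h]]
        W -= np.abs(Xs[hits] - Xs[i]).mean(axis=0)
        for c in classes:
            if c == ci:
                continue
            miss_idx = np.where(y == c)[0]
            k_m = min(k_neighbors, len(miss_idx))
            misses = miss_idx[np.argsort(D[i, miss_idx], kind="stable")[:k_m]]
            w_c = priors[c] / (1.0 - priors[ci])
            W += w_c * np.abs(Xs[misses] - Xs[i]).mean(axis=0)
    return W / n


def to_percentages(raw_scores) -> np.ndarray:
    """Convert raw scores to percentages of the positive-score total.

    Non-positive scores map to 0. If no score is positive, everything is 0
    (with a warning).
    """
    s = np.asarray(raw_scores, dtype=float)
    pos = np.where(s > 0, s, 0.0)
    total = pos.sum()
    if total <= 0:
        warnings.warn("to_percentages: no positive score; all percentages are 0")
        return np.zeros_like(s)
    return 100.0 * pos / total


def average_percentages(percentages: np.ndarray) -> np.ndarray:
    """Row-wise mean over methods of a (feature x method) percentage array.

    Methods whose score was non-positive contribute 0 (already encoded as a
    0 percentage), so the divisor is always the number of methods.
    """
    P = np.asarray(percentages, dtype=float)
    return P.mean(axis=1)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, m * p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def rank_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    k_neighbors: int = 10,
    n_bins: int = 10,
    log_base: str = "e",
    covariate_cols: tuple[str, ...] = ("age", "sex", "education", "icv"),
) -> pd.DataFrame:
    """Score every feature by every criterion.

    Returns a DataFrame indexed by feature with columns
    ``{method}_score``, ``{method}_pct``, ``{method}_p`` (where applicable),
    ``ancova_p``, and ``average_pct``.
    """
    feats = features if features is not None else feature_columns(table)
    labels = table["group"].to_numpy()
    cov = table.loc[:, list(covariate_cols)]
    rows = {}
    for f in feats:
        v = table[f].to_numpy(dtype=float)
        chi2_stat, chi2_p, chi2_s = chi2_score(v, labels, n_bins=n_bins, log_base=log_base)
        F, anova_p, anova_s = anova_score(v, labels, log_base=log_base)
        H, kw_p, kw_s = kruskal_score(v, labels, log_base=log_base)
        _, ancova_p = ancova_score(v, labels, cov)
        rows[f] = {
            "chi2_score": chi2_s, "chi2_p": chi2_p,
            "anova_score": anova_s, "anova_p": anova_p,
            "kruskal_score": kw_s, "kruskal_p": kw_p,
            "ancova_p": ancova_p,
        }
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores.index.name = "feature"
    W = relieff_score(table[feats].to_numpy(dtype=float), labels, k_neighbors=k_neighbors)
    scores["relieff_score"] = W
    for m in SCORE_METHODS:
        scores[f"{m}_pct"] = to_percentages(scores[f"{m}_score"].to_numpy())
    scores["average_pct"] = average_percentages(
        scores[[f"{m}_pct" for m in SCORE_METHODS]].to_numpy()
    )
    return scores


@dataclass
class FeatureSubsets:
    """The four derived feature subsets plus a per-feature selection tally."""

    subset_a: list[str]
    subset_b: list[str]
    subset_c: list[str]
    subset_d: list[str]
    provenance: pd.DataFrame = field(repr=False, default=None)

    def __getitem__(self, key: str) -> list[str]:
        return getattr(self, f"subset_{key.lower()}")

    def as_dict(self) -> dict[str, list[str]]:
        return {k: getattr(self, f"subset_{k}") for k in "abcd"}


def build_subsets(scores: pd.DataFrame, alpha: float = 0.05) -> FeatureSubsets:
    """Derive subsets A-D from a ``rank_features`` score table.

    Per-criterion selections mirror the tally construction: percentage at or
    above the method's median for chi-square/ANOVA/Kruskal-Wallis, strictly
    positive weight for ReliefF, the average-percentage rule (subset A), and
    the adjusted-significance rule (subset D). Subset C is their intersection.
    """
    feats = scores.index.to_list()
    sel: dict[str, pd.Series] = {}
    for m in ("chi2", "anova", "kruskal"):
        pct = scores[f"{m}_pct"]
        sel[m] = pct >= pct.median()
    sel["relieff"] = scores["relieff_score"] > 0

    avg = scores["average_pct"]
    sel["average"] = avg >= avg.median()

    m = len(feats)
    sig = pd.Series(True, index=scores.index)
    for test in ("anova", "ancova", "kruskal"):
        sig &= bonferroni_adjust(scores[f"{test}_p"].to_numpy(), m) <= alpha
    sel["significance"] = sig

    provenance = pd.DataFrame(sel)
    provenance["total"] = provenance.sum(axis=1)

    subset_a = [f for f in feats if sel["average"][f]]
    subset_b = [f for f in feats if sel["relieff"][f]]
    subset_c = [f for f in feats if provenance.loc[f, list(sel)].all()]
    subset_d = [f for f in feats if sig[f]]
    for name, s in zip("ABCD", (subset_a, subset_b, subset_c, subset_d)):
        if not s:
            logger.warning("build_subsets: subset %s is empty", name)
    return FeatureSubsets(subset_a, subset_b, subset_c, subset_d, provenance)
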