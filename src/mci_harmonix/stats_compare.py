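"""Statistical comparison of pipeline options.

Replication-level metric values are treated as independent observations (an
approximation: replications share the underlying data through resampled
partitions, so p-values are indicative rather than exact — the report says
so). Main tools: N-way ANOVA over the design factors, pairwise comparisons
under Bonferroni and Benjamini-Hochberg control, and Tukey's HSD
(Tukey-Kramer for unequal group sizes).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["nway_anova", "bh_fdr", "tukey_hsd", "compare_report"]

DEPENDENCE_NOTE = (
    "Replications share data through resampled partitions; p-values are "
    "approximate."
)


def nway_anova(
    design: pd.DataFrame,
    response: str,
    factors: list[str],
    interactions: bool = False,
) -> pd.DataFrame:
    """Least-squares N-way ANOVA (type II) of ``response`` on the factors.

    Returns a table with sum_sq, df, F and p per term. Factors with a single
    level or aliased factors raise.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for f in factors:
        if design[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    df = design[[response] + factors].copy()
    df.columns = ["resp"] + [f"f{i}" for i in range(len(factors))]
    terms = [f"C(f{i})" for i in range(len(factors))]
    if interactions:
        terms += [
            f"C(f{i}):C(f{j})"
            for i, j in itertools.combinations(range(len(factors)), 2)
        ]
    if np.ptp(df["resp"].to_numpy(dtype=float)) == 0:
        # constant response: zero between-group variation by definition
        out = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0},
            index=factors + (["Residual"]),
        )
        return out.rename(columns={"PR(>F)": "p"})
    model = ols("resp ~ " + " + ".join(terms), data=df).fit()
    if model.df_resid < 1:
        raise ValueError("residual degrees of freedom < 1 (aliased or saturated)")
    table = sm.stats.anova_lm(model, typ=2)
    mapping = {f"C(f{i})": factors[i] for i in range(len(factors))}
    for i, j in itertools.combinations(range(len(factors)), 2):
        mapping[f"C(f{i}):C(f{j})"] = f"{factors[i]}:{factors[j]}"
    table.index = [mapping.get(ix, ix) for ix in table.index]
    return table.rename(columns={"PR(>F)": "p"})


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Rejects all hypotheses with p <= p_(k*), k* = max{k : p_(k) <= k q / m};
    adjusted p-values follow by cumulative-minimum monotonization. Returns
    (reject mask, adjusted p), both in the input order.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    thresh = ranked <= np.arange(1, m + 1) * q / m
    k_star = np.max(np.nonzero(thresh)[0]) + 1 if thresh.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k_star] = True
    reject = np.empty(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adj
    return reject, adjusted


def tukey_hsd(
    group_means,
    mse: float,
    group_sizes,
    alpha: float = 0.05,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise studentized-range tests from group summaries.

    Unequal sizes use the Tukey-Kramer standard error. ``mse`` is the pooled
    within-group mean square with df = sum(n_i) - k.
    """
    from scipy.stats import studentized_range

    means = np.asarray(group_means, dtype=float)
    sizes = np.asarray(group_sizes, dtype=int)
    k = len(means)
    if k < 2:
        raise ValueError("tukey_hsd requires >= 2 groups")
    if mse <= 0:
        raise ValueError("mse must be positive")
    names = names if names is not None else [f"g{i}" for i in range(k)]
    df = int(sizes.sum() - k)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(diff) / se
        p = float(studentized_range.sf(q, k, df))
        rows.append({
            "group1": names[i], "group2": names[j], "diff": diff,
            "q": q, "p": p, "significant": p <= alpha,
        })
    return pd.DataFrame(rows)


def compare_report(
    results: pd.DataFrame,
    metric: str,
    estimate_type: str = "nested",
    q: float = 0.05,
) -> dict:
    """Rank classifier/harmonization options on one metric with significance.

    Per-classifier comparisons pool the feature subsets; pairwise Welch tests
    across replication values are FDR-controlled at level ``q``. Returns a
    dict with the ranking table, the pairwise table and a dependence caveat.
    """
    sub = results[(results["metric"] == metric) & (results["estimate_type"] == estimate_type)]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r} ({estimate_type})")
    expected = {
        (c, h)
        for c in results["classifier"].unique()
        for h in results["harmonization"].unique()
    }
    present = set(map(tuple, sub[["classifier", "harmonization"]].drop_duplicates().to_numpy()))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"missing combinations for {metric!r}: {missing}")

    ranking = (
        sub.groupby(["classifier", "harmonization"])["value"]
        .agg(["mean", "std", "count"])
        .sort_values("mean", ascending=False)
        .reset_index()
    )

    pooled = {c: g["value"].to_numpy() for c, g in sub.groupby("classifier")}
    pairs, ps = [], []
    for a, b in itertools.combinations(sorted(pooled), 2):
        va, vb = pooled[a], pooled[b]
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
            p = 1.0
        else:
            _, p = stats.ttest_ind(va, vb, equal_var=False)
            p = 1.0 if not np.isfinite(p) else float(p)
        pairs.append((a, b))
        ps.append(p)
    reject, adj = bh_fdr(np.array(ps), q=q) if ps else (np.array([]), np.array([]))
    pairwise = pd.DataFrame({
        "classifier_1": [a for a, _ in pairs],
        "classifier_2": [b for _, b in pairs],
        "p": ps,
        "p_fdr": adj,
        "significant": reject,
    })
    return {"ranking": ranking, "pairwise": pairwise, "note": DEPENDENCE_NOTE}
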