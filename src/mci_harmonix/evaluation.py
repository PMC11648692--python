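"""Nested cross-validation with Bayesian hyperparameter optimization,
replicated by Monte Carlo, in balanced and imbalanced modes.

The outer loop holds out one stratified fold at a time for unbiased
performance estimation; on the remaining folds a sequential model-based
optimizer (Gaussian-process surrogate with expected-improvement acquisition;
pure random search available behind the same contract) minimizes the
cost-weighted misclassification rate of an inner (K-1)-fold cross-validation.
The selected configuration is refitted on the full outer-training data and
applied to the holdout; holdout predictions are pooled into one confusion
table per replication (fold-averaged metrics available by flag). The
inner-CV performance of the selected configuration is recorded alongside as
the optimism-prone "direct" estimate.

In imbalanced mode every classifier except RUSBoost is compensated with the
cost matrix [[0, 1], [delta, 0]], where delta is the majority/minority size
ratio computed on the outer-training fold. In balanced mode a fresh random
undersample of the majority class precedes nested CV in every replication.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from scipy.stats import norm

from .classifiers import ClassifierSpec, apply_cost_matrix, make_classifier, predict_scores
from .metrics import ConfusionTable, MetricSet, aroc, compute_metrics, confusion

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig",
    "ReplicationResult",
    "stratified_kfold",
    "undersample_majority",
    "delta",
    "bayes_opt",
    "nested_cv_evaluate",
    "monte_carlo_run",
]


@dataclass
class EvaluationConfig:
    """Knobs of the evaluation pipeline.

    Reference-scale values are K=10 outer folds, 20 Monte Carlo replications
    and 200 optimizer iterations; ``desk_scale`` ships a configuration sized
    for interactive runs and the test suite.
    """

    k_outer: int = 10
    mc_reps: int = 20
    opt_budget: int = 200
    mode: str = "imbalanced"
    master_seed: int = 0
    optimizer: str = "gp"  # 'gp' or 'random'
    pooling: str = "pooled"  # 'pooled' or 'fold_mean'

    def __post_init__(self):
        if self.k_outer < 2:
            raise ValueError("k_outer must be >= 2")
        if self.mode not in ("balanced", "imbalanced"):
            raise ValueError("mode must be 'balanced' or 'imbalanced'")
        if self.optimizer not in ("gp", "random"):
            raise ValueError("optimizer must be 'gp' or 'random'")
        if self.pooling not in ("pooled", "fold_mean"):
            raise ValueError("pooling must be 'pooled' or 'fold_mean'")

    @classmethod
    def desk_scale(cls, **overrides) -> "EvaluationConfig":
        base = dict(k_outer=5, mc_reps=5, opt_budget=30)
        base.update(overrides)
        return cls(**base)


@dataclass
class ReplicationResult:
    replication: int
    nested_confusion: ConfusionTable
    nested_metrics: MetricSet
    direct_metrics: MetricSet
    fold_params: list[dict]
    seed: int
    failed_folds: int = 0


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: per-class counts across folds differ by <= 1."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def undersample_majority(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomly subsample the majority group (without replacement) to the
    minority size; the minority group is untouched."""
    counts = table["group"].value_counts()
    if len(counts) < 2:
        raise ValueError("undersample_majority requires two groups")
    minority, majority = counts.idxmin(), counts.idxmax()
    if counts[minority] == counts[majority]:
        return table.copy()
    rng = np.random.default_rng(seed)
    maj_rows = table.index[table["group"] == majority].to_numpy()
    keep = rng.choice(maj_rows, size=int(counts[minority]), replace=False)
    out = table.loc[np.concatenate([keep, table.index[table["group"] == minority]])]
    return out.sort_index().reset_index(drop=True)


def delta(labels) -> float:
    """Majority/minority cardinality ratio (>= 1)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("delta requires both groups non-empty")
    return float(counts.max() / counts.min())


# ---------------------------------------------------------------------------
# Sequential model-based optimization
# ---------------------------------------------------------------------------


def _sample_params(space: list[dict], rng: np.random.Generator) -> dict:
    params = {}
    for p in space:
        if p["kind"] == "categorical":
            params[p["name"]] = p["categories"][rng.integers(len(p["categories"]))]
        elif p["kind"] == "integer":
            if p.get("log"):
                v = np.exp(rng.uniform(np.log(p["low"]), np.log(p["high"] + 1)))
                params[p["name"]] = int(min(int(v), p["high"]))
            else:
                params[p["name"]] = int(rng.integers(p["low"], p["high"] + 1))
        else:
            if p.get("log"):
                params[p["name"]] = float(np.exp(rng.uniform(np.log(p["low"]), np.log(p["high"]))))
            else:
                params[p["name"]] = float(rng.uniform(p["low"], p["high"]))
    return params


def _encode(space: list[dict], params: dict) -> np.ndarray:
    """Map a parameter dict to a [0,1]-scaled vector (one-hot categoricals,
    log scaling for log-bounded numerics)."""
    feats: list[float] = []
    for p in space:
        v = params[p["name"]]
        if p["kind"] == "categorical":
            feats.extend(1.0 if v == c else 0.0 for c in p["categories"])
        else:
            lo, hi = p["low"], p["high"]
            if p.get("log"):
                feats.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                feats.append((v - lo) / (hi - lo))
    return np.array(feats)


def bayes_opt(
    objective,
    space: list[dict],
    budget: int,
    seed: int,
    method: str = "gp",
    n_candidates: int = 256,
) -> tuple[dict, pd.DataFrame]:
    """Minimize ``objective`` over the space within ``budget`` evaluations.

    An initial random design of max(10, budget // 5) points (capped at the
    budget, in which case the procedure reduces to random search) seeds a
    Gaussian-process surrogate; subsequent points maximize expected
    improvement over random candidate draws. Returns the argmin of the
    observed objective and the evaluation trace.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    n_init = min(max(10, budget // 5), budget)
    evaluated: list[dict] = []
    values: list[float] = []

    def run(params):
        try:
            v = float(objective(params))
        except Exception as exc:  # classifier failure counts as a bad point
            logger.warning("bayes_opt: objective failed at %s (%s)", params, exc)
            v = np.nan
        evaluated.append(params)
        values.append(v)

    for _ in range(n_init):
        run(_sample_params(space, rng))

    if method == "gp" and budget > n_init:
        kernel = ConstantKernel(1.0) * RBF(length_scale=0.5) + WhiteKernel(1e-4)
        while len(values) < budget:
            vals = np.asarray(values)
            finite = np.isfinite(vals)
            if finite.sum() < len(vals) / 2 and len(vals) >= 10:
                raise RuntimeError("objective non-finite at > 50% of evaluations")
            if finite.sum() < 2:
                run(_sample_params(space, rng))
                continue
            worst = vals[finite].max()
            y = np.where(finite, vals, worst)
            X = np.array([_encode(space, p) for p in evaluated])
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True, n_restarts_optimizer=0,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X, y)
            cands = [_sample_params(space, rng) for _ in range(n_candidates)]
            Xc = np.array([_encode(space, p) for p in cands])
            mu, sd = gp.predict(Xc, return_std=True)
            best = y.min()
            sd = np.maximum(sd, 1e-12)
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            run(cands[int(np.argmax(ei))])
    else:
        while len(values) < budget:
            run(_sample_params(space, rng))

    vals = np.asarray(values)
    if not np.isfinite(vals).any():
        raise RuntimeError("objective returned no finite value")
    best_idx = int(np.nanargmin(vals))
    trace = pd.DataFrame({"params": evaluated, "objective": values})
    return evaluated[best_idx], trace


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


def _weighted_error(y_true, y_pred, d: float, positive: str = "uHC") -> float:
    """Cost-weighted misclassification rate with minority errors weighted d."""
    y_true = np.asarray(y_true)
    wrong = (y_true != np.asarray(y_pred)).astype(float)
    w = np.where(y_true == positive, d, 1.0)
    return float((w * wrong).sum() / w.sum())


def _inner_cv_predictions(X, y, spec, params, k_inner, seed):
    """Pooled predictions of an inner (K-1)-fold cross-validation."""
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for tr, te in skf.split(X, y):
        model = make_classifier(spec, params, seed=seed)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return pred.astype(str)


def nested_cv_evaluate(
    table: pd.DataFrame,
    features: list[str],
    spec: ClassifierSpec,
    config: EvaluationConfig,
    seed: int,
    replication: int = 0,
) -> ReplicationResult:
    """One replication of nested CV for one (data, features, classifier) triple."""
    if not features:
        raise ValueError("feature subset is empty")
    X = table[features].to_numpy(dtype=float)
    y = table["group"].to_numpy().astype(str)
    k = config.k_outer
    k_inner = max(k - 1, 2)
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    pooled_pred = np.empty(len(y), dtype=object)
    pooled_scores = np.full(len(y), np.nan)
    seen = np.zeros(len(y), dtype=int)
    fold_params: list[dict] = []
    fold_tables: list[ConfusionTable] = []
    direct_true: list[np.ndarray] = []
    direct_pred: list[np.ndarray] = []
    failed = 0

    for fold, (tr, te) in enumerate(outer.split(X, y)):
        fold_seed = (seed * 1000 + fold) % (2**31 - 1)
        if config.mode == "imbalanced":
            spec_fold = apply_cost_matrix(spec, delta(y[tr]))
        else:
            spec_fold = apply_cost_matrix(spec, 1.0)
        d = spec_fold.delta

        def objective(params, tr=tr, spec_fold=spec_fold, d=d, fold_seed=fold_seed):
            pred = _inner_cv_predictions(X[tr], y[tr], spec_fold, params, k_inner, fold_seed)
            return _weighted_error(y[tr], pred, d)

        try:
            if spec.space:
                best, _ = bayes_opt(
                    objective, spec.space, config.opt_budget, fold_seed,
                    method=config.optimizer,
                )
            else:
                best = {}
            model = make_classifier(spec_fold, best, seed=fold_seed)
            model.fit(X[tr], y[tr])
            pooled_pred[te] = model.predict(X[te])
            try:
                pooled_scores[te] = predict_scores(model, X[te])
            except (AttributeError, ValueError):
                pass
            seen[te] += 1
            fold_params.append(best)
            fold_tables.append(confusion(y[te], pooled_pred[te].astype(str)))
            # direct (optimism-prone) estimate: inner-CV predictions of the
            # configuration that was selected
            dp = _inner_cv_predictions(X[tr], y[tr], spec_fold, best, k_inner, fold_seed)
            direct_true.append(y[tr])
            direct_pred.append(dp)
            logger.info(
                "fold %d: params=%s holdout n=%d", fold, best, len(te)
            )
        except Exception as exc:
            failed += 1
            logger.warning("nested_cv_evaluate: fold %d failed (%s)", fold, exc)

    if failed == k:
        raise RuntimeError("every outer fold failed")
    predicted = seen > 0
    if failed == 0 and not np.all(seen == 1):
        raise AssertionError("holdout integrity breach: a sample was predicted != once")

    nested_ct = confusion(y[predicted], pooled_pred[predicted].astype(str))
    have_scores = predicted & np.isfinite(pooled_scores)
    nested_aroc = None
    if have_scores.sum() > 1 and len(set(y[have_scores])) == 2:
        nested_aroc = aroc(pooled_scores[have_scores], y[have_scores])
    if config.pooling == "pooled":
        nested_metrics = compute_metrics(nested_ct)
    else:
        per_fold = [compute_metrics(ct) for ct in fold_tables]
        vals = {
            k2: float(np.mean([getattr(m, k2) for m in per_fold]))
            for k2 in ("acc", "f1", "mcc", "tpr", "tnr", "ppv", "npv")
        }
        nested_metrics = MetricSet(mcc_prime=0.5 * (1 + vals["mcc"]), **vals)
    if nested_aroc is not None:
        nested_metrics = MetricSet(**{**nested_metrics.as_dict(), "aroc": nested_aroc,
                                      "degenerate": nested_metrics.degenerate})

    direct_ct = confusion(np.concatenate(direct_true), np.concatenate(direct_pred))
    direct_metrics = compute_metrics(direct_ct)

    return ReplicationResult(
        replication=replication,
        nested_confusion=nested_ct,
        nested_metrics=nested_metrics,
        direct_metrics=direct_metrics,
        fold_params=fold_params,
        seed=seed,
        failed_folds=failed,
    )


# ---------------------------------------------------------------------------
# Monte Carlo driver
# ---------------------------------------------------------------------------


def _derive_seed(master_seed: int, replication: int, combo_index: int) -> int:
    ss = np.random.SeedSequence(entropy=(master_seed, replication, combo_index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def monte_carlo_run(
    datasets: dict[str, pd.DataFrame],
    harmonizations: list[str],
    subsets: dict[str, list[str]],
    classifiers: list[ClassifierSpec],
    config: EvaluationConfig,
) -> pd.DataFrame:
    """Replicated factorial evaluation over
    (dataset x harmonization x subset x classifier).

    Dataset values are uncorrected feature tables; each requested
    harmonization is fitted once per dataset on its reference group. In
    balanced mode a fresh undersample precedes nested CV in every
    replication. Returns the long-format results table.
    """
    from .harmonization import PolynomialHarmonizer

    prepared: dict[tuple[str, str], pd.DataFrame] = {}
    for dname, table in datasets.items():
        needed = sorted({f for fl in subsets.values() for f in fl})
        for h in harmonizations:
            harm = PolynomialHarmonizer(method=h, features=needed)
            prepared[(dname, h)] = harm.fit(table).transform(table)

    combos = [
        (dname, h, sname, spec)
        for dname in datasets
        for h in harmonizations
        for sname in subsets
        for spec in classifiers
    ]
    rows = []
    for rep in range(config.mc_reps):
        for ci, (dname, h, sname, spec) in enumerate(combos):
            seed = _derive_seed(config.master_seed, rep, ci)
            data = prepared[(dname, h)]
            if config.mode == "balanced":
                data = undersample_majority(data, seed)
            feats = subsets[sname]
            if not feats:
                logger.warning("skipping empty subset %s", sname)
                continue
            result = nested_cv_evaluate(
                data, feats, spec, config, seed=seed, replication=rep
            )
            for est_type, ms in (
                ("nested", result.nested_metrics),
                ("direct", result.direct_metrics),
            ):
                for metric, value in ms.as_dict().items():
                    rows.append({
                        "replication": rep,
                        "dataset": dname,
                        "harmonization": h,
                        "subset": sname,
                        "classifier": spec.family,
                        "mode": config.mode,
                        "estimate_type": est_type,
                        "metric": metric,
                        "value": value,
                    })
    return pd.DataFrame(rows)
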