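"""Reference-group polynomial covariate harmonization.

For each volumetric feature, a polynomial surface in (age, ICV) is fitted by
ordinary least squares to the reference group (stable controls) separately
per sex. Every subject's value is then corrected with the model of their sex:

* residual harmonization:  x1 = y - mu_hat
* z-score harmonization:   x2 = (y - mu_hat) / sigma_hat

where mu_hat is the fitted surface mean at the subject's (age, ICV) and
sigma_hat is the prediction standard deviation. By default sigma_hat is the
observation-level prediction sd, sqrt(mse * (1 + x0' (X'X)^-1 x0)); a
mean-level variant, sqrt(mse * x0' (X'X)^-1 x0), is available by flag.

Non-reference rows (converters) are always corrected with the reference-
fitted model of their sex; the model is never refitted on them. Queries
outside the reference covariate hull are permitted but logged, since the
surface is extrapolating where reference points are scarce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import SEX_LABELS, feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "PolySurfaceModel",
    "PolynomialHarmonizer",
    "fit_reference_model",
    "predict_mean_sd",
    "harmonize",
]

_DEGREE_NAMES = ("poly11", "poly22")
_ZSCORE_SD_TOL = 1e-10


def _design(age: np.ndarray, icv: np.ndarray, degree: str) -> np.ndarray:
    """Monomial design matrix: poly11 -> [1, age, icv]; poly22 adds
    [age^2, age*icv, icv^2]."""
    cols = [np.ones_like(age), age, icv]
    if degree == "poly22":
        cols += [age**2, age * icv, icv**2]
    return np.column_stack(cols)


@dataclass
class PolySurfaceModel:
    """Per-sex OLS fit of one feature on (age, ICV) over the reference group."""

    sex_stratum: str
    degree: str
    coefficients: np.ndarray
    mse: float
    gram_inverse: np.ndarray
    n_ref: int
    # reference covariate hull, for extrapolation flagging
    age_range: tuple[float, float] = (-np.inf, np.inf)
    icv_range: tuple[float, float] = (-np.inf, np.inf)

    def predict(self, age, icv, sd_mode: str = "observation"):
        return predict_mean_sd(self, age, icv, sd_mode=sd_mode)


def fit_reference_model(
    table: pd.DataFrame,
    feature: str,
    degree: str = "poly11",
    reference_group: str = "HC",
) -> dict[str, PolySurfaceModel]:
    """Fit one surface per sex on the reference group only.

    Requires at least p + 2 reference rows per sex (p = coefficient count).
    Returns ``{"Male": model, "Female": model}``.
    """
    if degree not in _DEGREE_NAMES:
        raise ValueError(f"degree must be one of {_DEGREE_NAMES}")
    ref = table[table["group"] == reference_group]
    models: dict[str, PolySurfaceModel] = {}
    p = 3 if degree == "poly11" else 6
    for sex in SEX_LABELS:
        sub = ref[ref["sex"] == sex]
        if len(sub) < p + 2:
            raise ValueError(
                f"{feature}/{sex}: {len(sub)} reference rows < required {p + 2}"
            )
        age = sub["age"].to_numpy(dtype=float)
        icv = sub["icv"].to_numpy(dtype=float)
        y = sub[feature].to_numpy(dtype=float)
        X = _design(age, icv, degree)
        # column equilibration + QR: the (age, ICV) monomials span ~12 orders
        # of magnitude, so solve on unit-norm columns and rescale after
        d = np.linalg.norm(X, axis=0)
        Q, R = np.linalg.qr(X / d)
        if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
            raise np.linalg.LinAlgError(f"{feature}/{sex}: rank-deficient design")
        beta = np.linalg.solve(R, Q.T @ y) / d
        resid = y - X @ beta
        mse = float(resid @ resid) / (len(y) - p)
        r_inv = np.linalg.solve(R, np.eye(p)) / d[:, None]
        gram_inverse = r_inv @ r_inv.T  # (X'X)^-1 = R^-1 R^-T (rescaled)
        models[sex] = PolySurfaceModel(
            sex_stratum=sex,
            degree=degree,
            coefficients=beta,
            mse=mse,
            gram_inverse=gram_inverse,
            n_ref=len(y),
            age_range=(float(age.min()), float(age.max())),
            icv_range=(float(icv.min()), float(icv.max())),
        )
    return models


def predict_mean_sd(
    model: PolySurfaceModel,
    age,
    icv,
    sd_mode: str = "observation",
):
    """Surface mean and prediction sd at (age, icv).

    ``sd_mode='observation'`` returns sqrt(mse * (1 + leverage)), the sd of a
    new observation; ``'mean'`` returns sqrt(mse * leverage), the sd of the
    fitted mean itself.
    """
    if sd_mode not in ("observation", "mean"):
        raise ValueError("sd_mode must be 'observation' or 'mean'")
    age = np.atleast_1d(np.asarray(age, dtype=float))
    icv = np.atleast_1d(np.asarray(icv, dtype=float))
    out_of_hull = (
        (age < model.age_range[0]) | (age > model.age_range[1])
        | (icv < model.icv_range[0]) | (icv > model.icv_range[1])
    )
    if np.any(out_of_hull):
        logger.info(
            "predict_mean_sd: %d/%d queries outside the %s reference hull "
            "(extrapolating)", int(out_of_hull.sum()), len(age), model.sex_stratum,
        )
    X0 = _design(age, icv, model.degree)
    mu = X0 @ model.coefficients
    leverage = np.einsum("ij,jk,ik->i", X0, model.gram_inverse, X0)
    offset = 1.0 if sd_mode == "observation" else 0.0
    sigma = np.sqrt(np.maximum(model.mse * (offset + leverage), 0.0))
    if np.isscalar(age) or mu.shape == (1,):
        return float(mu[0]), float(sigma[0])
    return mu, sigma


def harmonize(
    table: pd.DataFrame,
    models: dict[str, dict[str, PolySurfaceModel]],
    method: str = "residual",
    sd_mode: str = "observation",
) -> pd.DataFrame:
    """Apply fitted per-(feature, sex) models to every row of the table.

    ``models`` maps feature -> sex -> PolySurfaceModel. Row order and ids are
    preserved; the returned frame carries a ``harmonization`` attribute tag.
    """
    if method not in ("residual", "zscore"):
        raise ValueError("method must be 'residual' or 'zscore'")
    out = table.copy()
    age = table["age"].to_numpy(dtype=float)
    icv = table["icv"].to_numpy(dtype=float)
    sex = table["sex"].to_numpy()
    for feature, per_sex in models.items():
        y = table[feature].to_numpy(dtype=float)
        corrected = np.empty_like(y)
        for s in SEX_LABELS:
            mask = sex == s
            if not mask.any():
                continue
            mu, sigma = predict_mean_sd(per_sex[s], age[mask], icv[mask], sd_mode=sd_mode)
            if method == "residual":
                corrected[mask] = y[mask] - mu
            else:
                if np.any(sigma < _ZSCORE_SD_TOL):
                    raise ValueError(
                        f"{feature}/{s}: prediction sd below tolerance for z-scoring"
                    )
                corrected[mask] = (y[mask] - mu) / sigma
        out[feature] = corrected
    out.attrs["harmonization"] = method
    return out


class PolynomialHarmonizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: fit on the reference group, transform anyone.

    Parameters
    ----------
    method : {'residual', 'zscore', 'uncorrected'}
        Correction applied at transform time; 'uncorrected' passes data through
        (tagged), so the harmonizer slots into pipelines uniformly.
    degree : {'poly11', 'poly22'}
        Polynomial surface degree in (age, ICV).
    reference_group : str
        Group label whose rows parameterize the surfaces (default 'HC').
    sd_mode : {'observation', 'mean'}
        Prediction-sd variant used for z-scoring.
    features : list of str, optional
        Columns to harmonize; default: every non-metadata column.
    """

    def __init__(
        self,
        method: str = "residual",
        degree: str = "poly11",
        reference_group: str = "HC",
        sd_mode: str = "observation",
        features: list[str] | None = None,
    ):
        self.method = method
        self.degree = degree
        self.reference_group = reference_group
        self.sd_mode = sd_mode
        self.features = features

    def fit(self, X: pd.DataFrame, y=None):
        if self.method not in ("residual", "zscore", "uncorrected"):
            raise ValueError(f"unknown method {self.method!r}")
        feats = self.features if self.features is not None else feature_columns(X)
        self.feature_names_ = list(feats)
        self.models_ = {}
        if self.method != "uncorrected":
            for feature in self.feature_names_:
                self.models_[feature] = fit_reference_model(
                    X, feature, degree=self.degree, reference_group=self.reference_group
                )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("PolynomialHarmonizer is not fitted")
        if self.method == "uncorrected":
            out = X.copy()
            out.attrs["harmonization"] = "uncorrected"
            return out
        return harmonize(X, self.models_, method=self.method, sd_mode=self.sd_mode)
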