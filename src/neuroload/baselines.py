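"""Linear comparators and univariate feature statistics.

Multiple linear regression (one weight per feature plus an intercept)
serves as the parametric baseline for the GP regressor.  Because raw
multivariate regression weights are hard to interpret under feature
collinearity, they can be transformed into activation patterns

    A = Sigma_x W Sigma_s^-1

where Sigma_x is the feature covariance of the data and Sigma_s the
variance of the latent factor (by default the model's fitted
predictions; optionally the label variance).  A classical per-feature
one-way ANOVA F statistic for the task-level factor provides the
conventional univariate relevance ranking that ARD length scales are
compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class MLRModel:
    weights: np.ndarray
    intercept: float

    @property
    def n_features(self) -> int:
        return len(self.weights)


def fit_mlr(X: np.ndarray, y: np.ndarray) -> MLRModel:
    """Ordinary least squares with an intercept.

    With fewer rows than features + 1 the system is underdetermined and
    the minimum-norm solution is returned with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("cannot fit regression on zero rows")
    if X.shape[0] != len(y):
        raise ValueError("X and y row counts differ")
    if X.shape[0] < X.shape[1] + 1:
        log.warning("underdetermined regression (%d rows, %d features); "
                    "returning the minimum-norm solution",
                    X.shape[0], X.shape[1])
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(weights=coef[1:], intercept=float(coef[0]))


def predict_mlr(model: MLRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension mismatch")
    return model.intercept + X @ model.weights


@dataclass
class ActivationPattern:
    """Haufe-style activation values, one per feature."""

    A: np.ndarray
    feature_covariance: np.ndarray
    latent_variance: float


def activation_pattern(model: MLRModel, X: np.ndarray,
                       y_hat: np.ndarray) -> ActivationPattern:
    """A = Sigma_x W / var(latent factor).

    ``y_hat`` is the latent factor — typically the model's fitted
    predictions on the data whose covariance is used (pass the labels
    instead to use label variance).  Equivalently, A equals the
    covariance of each feature with the latent factor divided by the
    latent variance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if X.shape[0] != len(y_hat):
        raise ValueError("X and y_hat row counts differ")
    sigma_x = np.cov(X, rowvar=False, ddof=1)
    sigma_x = np.atleast_2d(sigma_x)
    latent_var = float(np.var(y_hat, ddof=1))
    if latent_var == 0.0:
        raise ValueError("latent factor has zero variance")
    A = sigma_x @ model.weights / latent_var
    return ActivationPattern(A=np.asarray(A).ravel(),
                             feature_covariance=sigma_x,
                             latent_variance=latent_var)


@dataclass
class FeatureANOVA:
    """Per-feature one-way F statistics with a descending-F ranking."""

    f_values: np.ndarray
    feature_names: list[str] | None = None

    def ranking(self) -> pd.DataFrame:
        order = np.argsort(-self.f_values, kind="stable")
        names = (self.feature_names if self.feature_names is not None
                 else [f"f{i}" for i in range(len(self.f_values))])
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        frame = pd.DataFrame({
            "feature": names,
            "feature_index": np.arange(len(self.f_values)),
            "F": self.f_values,
            "rank": ranks,
        })
        return frame.sort_values("rank").reset_index(drop=True)


def anova_f_per_feature(X: np.ndarray, groups: np.ndarray,
                        feature_names: list[str] | None = None) -> FeatureANOVA:
    """Classical one-way ANOVA F per feature for a grouping factor.

    F = MS_between / MS_within with the usual degrees of freedom.  Needs
    at least two groups; if any group has fewer than two members the F
    values are flagged missing (NaN) since the within-group variance is
    not estimable on the usual footing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups).ravel()
    if len(groups) != X.shape[0]:
        raise ValueError("groups must align with rows of X")
    uniq, inverse, counts = np.unique(groups, return_inverse=True,
                                      return_counts=True)
    k = len(uniq)
    n = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        log.warning("a group has fewer than 2 members; F flagged missing")
        return FeatureANOVA(f_values=np.full(X.shape[1], np.nan),
                            feature_names=feature_names)
    grand = X.mean(axis=0)
    group_sums = np.zeros((k, X.shape[1]))
    np.add.at(group_sums, inverse, X)
    group_means = group_sums / counts[:, None]
    ss_between = (counts[:, None] * (group_means - grand) ** 2).sum(axis=0)
    ss_within = ((X - group_means[inverse]) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_within > 0, ms_between / np.where(ms_within > 0,
                                                          ms_within, 1.0),
                     np.inf)
    f = np.where((ms_within == 0) & (ms_between == 0), 0.0, f)
    return FeatureANOVA(f_values=f, feature_names=feature_names)
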