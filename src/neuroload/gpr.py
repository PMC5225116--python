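"""Exact Gaussian process regression with an ARD squared-exponential kernel.

The model is a zero-mean GP with covariance

    k(x_p, x_q) = sigma_f^2 * exp(-1/2 (x_p - x_q)^T diag(l)^-2 (x_p - x_q))

and a Gaussian likelihood with noise variance sigma_n^2.  One length
scale per feature (automatic relevance determination): after training, a
short length scale marks a feature the model is sensitive to, a long one
a feature it is nearly invariant to.

Hyperparameters are optimized on the log scale by minimizing the
negative log marginal likelihood

    NLML = 1/2 y^T (K + sigma_n^2 I)^-1 y + 1/2 log|K + sigma_n^2 I|
           + n/2 log 2 pi

with analytic gradients, using a deterministic quasi-Newton (L-BFGS-B)
minimizer under a fixed function-evaluation budget (default 100, the
budget used throughout this package; it counts objective/gradient
evaluations including line-search trials).  All linear algebra goes
through a Cholesky factorization of K + sigma_n^2 I with escalating
jitter — never an explicit inverse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

DEFAULT_INIT_LENGTH_SCALE = 10.0
DEFAULT_INIT_SIGNAL_VARIANCE = 1.0
DEFAULT_INIT_NOISE_VARIANCE = 1.0
DEFAULT_MAX_FUNCTION_EVALS = 100

_JITTER_START_FRAC = 1e-10
_JITTER_GROWTH = 10.0
_JITTER_MAX_RETRIES = 3


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel and likelihood hyperparameters, stored on the log scale."""

    log_length_scales: np.ndarray
    log_signal_variance: float
    log_noise_variance: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "log_length_scales",
            np.atleast_1d(np.asarray(self.log_length_scales, dtype=float)),
        )
        if not np.all(np.isfinite(self.log_length_scales)):
            raise ValueError("length scales must be finite and positive")

    @property
    def length_scales(self) -> np.ndarray:
        return np.exp(self.log_length_scales)

    @property
    def signal_variance(self) -> float:
        return float(np.exp(self.log_signal_variance))

    @property
    def noise_variance(self) -> float:
        return float(np.exp(self.log_noise_variance))

    @property
    def n_features(self) -> int:
        return len(self.log_length_scales)

    @classmethod
    def default(
        cls,
        n_features: int,
        length_scale: float = DEFAULT_INIT_LENGTH_SCALE,
        signal_variance: float = DEFAULT_INIT_SIGNAL_VARIANCE,
        noise_variance: float = DEFAULT_INIT_NOISE_VARIANCE,
    ) -> "GPHyperparams":
        return cls(
            log_length_scales=np.full(n_features, np.log(length_scale)),
            log_signal_variance=float(np.log(signal_variance)),
            log_noise_variance=float(np.log(noise_variance)),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.log_length_scales,
            [self.log_signal_variance, self.log_noise_variance],
        ])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "GPHyperparams":
        theta = np.asarray(theta, dtype=float)
        return cls(log_length_scales=theta[:-2],
                   log_signal_variance=float(theta[-2]),
                   log_noise_variance=float(theta[-1]))

    def subset(self, indices) -> "GPHyperparams":
        return replace(self, log_length_scales=self.log_length_scales[indices])


def se_ard_kernel(xp: np.ndarray, xq: np.ndarray, hyper: GPHyperparams) -> float:
    """Scalar ARD squared-exponential covariance between two feature vectors."""
    xp = np.asarray(xp, dtype=float).ravel()
    xq = np.asarray(xq, dtype=float).ravel()
    if xp.shape != xq.shape or len(xp) != hyper.n_features:
        raise ValueError("feature dimension mismatch with hyperparameters")
    z = (xp - xq) / hyper.length_scales
    return hyper.signal_variance * float(np.exp(-0.5 * z @ z))


def gram_matrix(X1: np.ndarray, X2: np.ndarray, hyper: GPHyperparams) -> np.ndarray:
    """Covariance matrix K with K[i, j] = k(X1[i], X2[j])."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1] or X1.shape[1] != hyper.n_features:
        raise ValueError("feature dimension mismatch with hyperparameters")
    ls = hyper.length_scales
    # A length scale underflowing to 0 is the infinitely-sensitive
    # limit: the division yields inf distances and exp(-inf) = 0.
    with np.errstate(divide="ignore"):
        sq = cdist(X1 / ls, X2 / ls, metric="sqeuclidean")
    return hyper.signal_variance * np.exp(-0.5 * sq)


def _cholesky_with_jitter(Ky: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of Ky, adding escalating diagonal jitter.

    Starts at 1e-10 x mean diagonal, grows tenfold, at most 3 retries;
    failure after retries raises rather than silently degrading.
    """
    jitter = 0.0
    base = _JITTER_START_FRAC * float(np.mean(np.diag(Ky)))
    for attempt in range(_JITTER_MAX_RETRIES + 1):
        try:
            L = cholesky(Ky + jitter * np.eye(len(Ky)), lower=True)
            if jitter > 0:
                log.warning("Cholesky required jitter %.3e", jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = base if jitter == 0.0 else jitter * _JITTER_GROWTH
    raise np.linalg.LinAlgError(
        f"covariance matrix not positive definite after jitter up to {jitter:.3e}"
    )


def negative_log_marginal_likelihood(
    hyper: GPHyperparams, X: np.ndarray, y: np.ndarray,
    with_grad: bool = True,
):
    """NLML of the zero-mean GP, optionally with its gradient.

    The gradient is taken with respect to the log-scale vector
    ``(log l_1..d, log sigma_f^2, log sigma_n^2)`` and matches central
    finite differences.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 1 or X.shape[0] != n:
        raise ValueError("X and y must align with n >= 1 rows")
    K = gram_matrix(X, X, hyper)
    sn2 = hyper.noise_variance
    Ky = K + sn2 * np.eye(n)
    L, _ = _cholesky_with_jitter(Ky)
    alpha = cho_solve((L, True), y)
    nlml = (0.5 * float(y @ alpha)
            + float(np.sum(np.log(np.diag(L))))
            + 0.5 * n * np.log(2.0 * np.pi))
    if not with_grad:
        return nlml

    # dNLML/dtheta = 1/2 tr((Ky^-1 - alpha alpha^T) dKy/dtheta)
    Kinv = cho_solve((L, True), np.eye(n))
    M = Kinv - np.outer(alpha, alpha)
    P = M * K
    g_sf2 = 0.5 * float(P.sum())
    g_sn2 = 0.5 * sn2 * float(np.trace(M))
    # For each dimension d: sum_ij P_ij (x_id - x_jd)^2 expands into row
    # and column sums of P plus one dense product — O(n^2 d) total.
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Xsq = X ** 2
    cross = np.einsum("id,id->d", X, P @ X)
    q = r @ Xsq + c @ Xsq - 2.0 * cross
    g_ls = 0.5 * q / hyper.length_scales ** 2
    grad = np.concatenate([g_ls, [g_sf2, g_sn2]])
    return nlml, grad


@dataclass
class GPModel:
    """Trained GP: retained training data, hyperparameters, cached factors."""

    X: np.ndarray
    y: np.ndarray
    hyper: GPHyperparams
    feature_names: list[str] | None = None
    L: np.ndarray = field(repr=False, default=None)
    alpha: np.ndarray = field(repr=False, default=None)
    jitter: float = 0.0
    nlml_initial: float | None = None
    nlml_final: float | None = None

    @property
    def n_train(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _factorize(X: np.ndarray, y: np.ndarray, hyper: GPHyperparams):
    K = gram_matrix(X, X, hyper)
    Ky = K + hyper.noise_variance * np.eye(len(y))
    L, jitter = _cholesky_with_jitter(Ky)
    alpha = cho_solve((L, True), y)
    return L, alpha, jitter


def train_gpr(
    X: np.ndarray,
    y: np.ndarray,
    init_hyper: GPHyperparams | None = None,
    max_function_evals: int = DEFAULT_MAX_FUNCTION_EVALS,
    feature_names: list[str] | None = None,
) -> GPModel:
    """Fit hyperparameters by NLML minimization from fixed defaults.

    Defaults: every length scale 10, signal variance 1, noise variance 1.
    The optimizer is budgeted at ``max_function_evals`` objective
    evaluations; if it fails to improve on the initial point the initial
    hyperparameters are kept, so the final NLML never exceeds the
    initial one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y row counts differ")
    if init_hyper is None:
        init_hyper = GPHyperparams.default(X.shape[1])
    if init_hyper.n_features != X.shape[1]:
        raise ValueError("init_hyper dimensionality mismatch")

    theta0 = init_hyper.to_vector()
    f0 = negative_log_marginal_likelihood(init_hyper, X, y, with_grad=False)
    if not np.isfinite(f0):
        raise ValueError(f"NLML not finite at initialization: {f0}")

    def objective(theta):
        hyper = GPHyperparams.from_vector(theta)
        try:
            return negative_log_marginal_likelihood(hyper, X, y)
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            # Extreme proposals (overflowing variances, non-PD K) are
            # treated as infinitely bad; the line search backtracks.
            return np.inf, np.zeros_like(theta)

    result = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxfun": max_function_evals,
                 "maxiter": max_function_evals,
                 "ftol": 1e-9, "gtol": 1e-6},
    )
    if np.isfinite(result.fun) and result.fun <= f0:
        hyper = GPHyperparams.from_vector(result.x)
        f_final = float(result.fun)
    else:  # optimizer failed to improve; keep the initialization
        log.warning("NLML optimization did not improve on the initial point")
        hyper, f_final = init_hyper, f0
    L, alpha, jitter = _factorize(X, y, hyper)
    return GPModel(X=X, y=y, hyper=hyper, feature_names=feature_names,
                   L=L, alpha=alpha, jitter=jitter,
                   nlml_initial=float(f0), nlml_final=f_final)


def make_model(X, y, hyper: GPHyperparams,
               feature_names: list[str] | None = None) -> GPModel:
    """Assemble a model with fixed (untrained) hyperparameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    L, alpha, jitter = _factorize(X, y, hyper)
    return GPModel(X=X, y=y, hyper=hyper, feature_names=feature_names,
                   L=L, alpha=alpha, jitter=jitter)


@dataclass
class PredictionSet:
    """Posterior summaries per test trial.

    ``var_latent`` is diag cov(f*); ``var_observed`` adds the noise
    variance and is what the plotted +/-2 sigma band uses.
    """

    mean: np.ndarray
    var_latent: np.ndarray
    var_observed: np.ndarray
    truth: np.ndarray | None = None

    @property
    def interval_halfwidth(self) -> np.ndarray:
        return 2.0 * np.sqrt(self.var_observed)

    def __len__(self) -> int:
        return len(self.mean)


def predict(model: GPModel, Xstar: np.ndarray,
            include_observation_noise: bool = True) -> PredictionSet:
    """Posterior mean and variance at test inputs.

    mean = K(X*, X) [K(X, X) + sigma_n^2 I]^-1 y, with the variance from
    the matching posterior-covariance diagonal; solved via the cached
    Cholesky factor.  Negative variances from round-off are clamped to 0.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.n_features:
        raise ValueError("test feature dimension mismatch")
    Ks = gram_matrix(Xstar, model.X, model.hyper)
    mean = Ks @ model.alpha
    v = solve_triangular(model.L, Ks.T, lower=True)
    var_latent = model.hyper.signal_variance - np.sum(v ** 2, axis=0)
    if np.any(var_latent < 0):
        log.warning("clamping %d negative predictive variances to 0",
                    int(np.sum(var_latent < 0)))
        var_latent = np.maximum(var_latent, 0.0)
    var_observed = var_latent + model.hyper.noise_variance
    return PredictionSet(mean=mean, var_latent=var_latent,
                         var_observed=var_observed)


def predict_with_feature_subset(
    model: GPModel, Xstar: np.ndarray, retained_features,
    refit: bool = False,
    max_function_evals: int = DEFAULT_MAX_FUNCTION_EVALS,
) -> PredictionSet:
    """Predict using only a subset of the trained model's features.

    The kernel is evaluated over the retained dimensions with their
    trained length scales, and training inputs restricted to the same
    columns; by default hyperparameters are *not* refit, exercising the
    model's robustness to missing features.  ``refit=True`` re-optimizes
    on the reduced representation instead.  ``Xstar`` must carry the full
    feature dimension; columns are selected internally.
    """
    idx = np.asarray(retained_features)
    if idx.dtype == bool:
        idx = np.nonzero(idx)[0]
    idx = idx.astype(int)
    if idx.size == 0:
        raise ValueError("retained feature subset must be nonempty")
    if np.any(idx < 0) or np.any(idx >= model.n_features):
        raise ValueError("retained feature index out of range")
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.n_features:
        raise ValueError("Xstar must have the full feature dimension")
    sub_names = (None if model.feature_names is None
                 else [model.feature_names[i] for i in idx])
    if refit:
        sub = train_gpr(model.X[:, idx], model.y,
                        init_hyper=model.hyper.subset(idx),
                        max_function_evals=max_function_evals,
                        feature_names=sub_names)
    else:
        sub = make_model(model.X[:, idx], model.y, model.hyper.subset(idx),
                         feature_names=sub_names)
    return predict(sub, Xstar[:, idx])


def length_scales(model: GPModel):
    """Per-feature relevance: trained length scale and ascending rank.

    Shorter length scale = more relevant; ties break by feature index.
    Returns a pandas DataFrame ordered most-relevant first.
    """
    import pandas as pd

    ls = model.hyper.length_scales
    order = np.argsort(ls, kind="stable")
    names = (model.feature_names if model.feature_names is not None
             else [f"f{i}" for i in range(len(ls))])
    ranks = np.empty(len(ls), dtype=int)
    ranks[order] = np.arange(1, len(ls) + 1)
    frame = pd.DataFrame({
        "feature": names,
        "feature_index": np.arange(len(ls)),
        "length_scale": ls,
        "rank": ranks,
    })
    return frame.sort_values("rank").reset_index(drop=True)


MODEL_SCHEMA_VERSION = 1


def save_model(model: GPModel, directory) -> None:
    """Persist a model: JSON metadata plus .npy arrays for X and y."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "log_length_scales": model.hyper.log_length_scales.tolist(),
        "log_signal_variance": model.hyper.log_signal_variance,
        "log_noise_variance": model.hyper.log_noise_variance,
        "feature_names": model.feature_names,
        "nlml_initial": model.nlml_initial,
        "nlml_final": model.nlml_final,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    np.save(directory / "X.npy", model.X)
    np.save(directory / "y.npy", model.y)


def load_model(directory) -> GPModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {meta.get('schema_version')}")
    hyper = GPHyperparams(
        log_length_scales=np.asarray(meta["log_length_scales"]),
        log_signal_variance=meta["log_signal_variance"],
        log_noise_variance=meta["log_noise_variance"],
    )
    X = np.load(directory / "X.npy")
    y = np.load(directory / "y.npy")
    model = make_model(X, y, hyper, feature_names=meta["feature_names"])
    model.nlml_initial = meta.get("nlml_initial")
    model.nlml_final = meta.get("nlml_final")
    return model
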