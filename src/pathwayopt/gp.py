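"""Gaussian-process surrogate: kernel, marginal-likelihood fit, posterior.

The surrogate assigns a posterior mean and variance to every point of the
design grid given the replicate-mean observations collected so far.  The
kernel is Matern 5/2 with automatic relevance determination (one lengthscale
per gene, on unit coordinates) — the standard choice for black-box Bayesian
optimization, smooth enough for an ordered expression ladder without the
unrealistic infinite smoothness of the squared exponential (which is
available behind ``FitConfig.kernel = "rbf"``).

Hyperparameters (per-dimension lengthscales, signal variance, noise
variance) are set by maximizing the log marginal likelihood with a seeded
multi-start L-BFGS in log-space, on observations standardized to zero mean
and unit variance; the constant mean is fixed at 0 in standardized space.
Measurement error is modeled as homoskedastic Gaussian noise — the fitted
``noise_variance`` is how the optimizer "expects an error" in assay reads
and keeps posterior variance positive at evaluated points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .gridspace import DesignSpace, ValidationError, levels_to_unit
from .landscapes import Observation

__all__ = [
    "GPHyperparams",
    "FitConfig",
    "GPModel",
    "kernel",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit_gp",
    "posterior",
]

_SQRT5 = np.sqrt(5.0)
_LOG2PI = np.log(2.0 * np.pi)


class NumericalError(RuntimeError):
    """Gram matrix not positive definite even after jitter escalation."""


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel and noise hyperparameters (standardized-output scale).

    ``lengthscales`` are per-dimension, in unit coordinates; ``noise_variance``
    is the homoskedastic measurement-error variance.
    """

    lengthscales: tuple[float, ...]
    signal_variance: float = 1.0
    noise_variance: float = 1e-4
    constant_mean: float = 0.0

    def __post_init__(self):
        if any(l <= 0 for l in self.lengthscales):
            raise ValidationError("lengthscales must be positive")
        if self.signal_variance <= 0:
            raise ValidationError("signal_variance must be positive")
        if self.noise_variance < 0:
            raise ValidationError("noise_variance must be nonnegative")


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameter-fit settings (maximum marginal likelihood).

    Bounds are in standardized-output units and log-space is searched.
    ``restarts`` counts random restarts beyond the default/warm start.
    """

    kernel: str = "matern52"
    restarts: int = 10
    lengthscale_bounds: tuple[float, float] = (0.05, 5.0)
    signal_bounds: tuple[float, float] = (0.1, 10.0)
    noise_bounds: tuple[float, float] = (1e-6, 1.0)
    seed: int = 0
    mode: str = "mml"
    warm_start: GPHyperparams | None = None

    def __post_init__(self):
        if self.kernel not in ("matern52", "rbf"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.mode != "mml":
            raise ValidationError("only maximum-marginal-likelihood mode is implemented")


def _scaled_sq_dists(a: np.ndarray, b: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Per-dimension squared distances / lengthscale^2, summed: r^2 matrix."""
    as_, bs_ = a / ls, b / ls
    sq = (
        (as_**2).sum(axis=1)[:, None]
        + (bs_**2).sum(axis=1)[None, :]
        - 2.0 * as_ @ bs_.T
    )
    return np.maximum(sq, 0.0)


def _matern52(r: np.ndarray) -> np.ndarray:
    sr = _SQRT5 * r
    return (1.0 + sr + sr**2 / 3.0) * np.exp(-sr)


def kernel_matrix(a: np.ndarray, b: np.ndarray, hp: GPHyperparams,
                  kind: str = "matern52") -> np.ndarray:
    """Cross-covariance matrix between row sets ``a`` and ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1] or a.shape[1] != len(hp.lengthscales):
        raise ValidationError("dimension mismatch between points and lengthscales")
    ls = np.asarray(hp.lengthscales, dtype=float)
    r2 = _scaled_sq_dists(a, b, ls)
    if kind == "matern52":
        k = _matern52(np.sqrt(r2))
    elif kind == "rbf":
        k = np.exp(-0.5 * r2)
    else:
        raise ValidationError(f"unknown kernel {kind!r}")
    return hp.signal_variance * k


def kernel(a: Sequence[float], b: Sequence[float], hp: GPHyperparams,
           kind: str = "matern52") -> float:
    """Scalar covariance between two unit-coordinate vectors."""
    return float(kernel_matrix(np.asarray(a)[None, :], np.asarray(b)[None, :],
                               hp, kind)[0, 0])


def _chol_with_jitter(K: np.ndarray, noise_variance: float):
    """Cholesky of K + noise*I with jitter escalation 1e-8 -> 1e-4."""
    n = K.shape[0]
    eye = np.eye(n)
    for jitter in (0.0, 1e-8, 1e-6, 1e-4):
        try:
            L = linalg.cholesky(K + (noise_variance + jitter) * eye, lower=True)
            return L, jitter
        except linalg.LinAlgError:
            continue
    raise NumericalError(
        f"Gram matrix not positive definite (n={n}, noise={noise_variance:.3g}) "
        "even with jitter up to 1e-4"
    )


def log_marginal_likelihood(points: np.ndarray, values: np.ndarray,
                            hp: GPHyperparams, kind: str = "matern52") -> float:
    """log p(y | X, theta) for y centered by the constant mean."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    y = np.asarray(values, dtype=float) - hp.constant_mean
    n = len(y)
    if n < 1:
        raise ValidationError("need at least one training pair")
    K = kernel_matrix(X, X, hp, kind)
    L, _ = _chol_with_jitter(K, hp.noise_variance)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * _LOG2PI
    )


def _lml_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                  kind: str) -> tuple[float, np.ndarray]:
    """Negative LML and its gradient w.r.t. log-hyperparameters.

    theta = (log ls_1..d, log signal_var, log noise_var); y pre-centered.
    """
    d = X.shape[1]
    ls = np.exp(theta[:d])
    sig = np.exp(theta[d])
    noi = np.exp(theta[d + 1])
    n = len(y)

    Xs = X / ls
    diffs_sq = (Xs[:, None, :] - Xs[None, :, :]) ** 2  # (n, n, d)
    r2 = diffs_sq.sum(axis=2)
    if kind == "matern52":
        r = np.sqrt(np.maximum(r2, 0.0))
        sr = _SQRT5 * r
        E = np.exp(-sr)
        M = (1.0 + sr + sr**2 / 3.0) * E
        # dK/dlog(ls_j) = sig * (5/3)(1 + sqrt5 r) e^{-sqrt5 r} * s_j
        dM_common = (5.0 / 3.0) * (1.0 + sr) * E
    else:
        M = np.exp(-0.5 * r2)
        dM_common = M  # dK/dlog(ls_j) = sig * M * s_j

    K = sig * M
    try:
        L, _ = _chol_with_jitter(K, noi)
    except NumericalError:
        return 1e25, np.zeros_like(theta)
    alpha = linalg.cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * _LOG2PI

    Kinv = linalg.cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # d(lml)/dK = A/2

    grad = np.empty_like(theta)
    W = sig * dM_common
    for j in range(d):
        grad[j] = 0.5 * (A * (W * diffs_sq[:, :, j])).sum()
    grad[d] = 0.5 * (A * K).sum()
    grad[d + 1] = 0.5 * noi * np.trace(A)
    return -float(lml), -grad


@dataclass(frozen=True, eq=False)
class GPModel:
    """A fitted surrogate, holding the solved state for posterior queries.

    Training outputs are standardized internally; :func:`posterior` returns
    de-standardized means and variances.  Posterior queries after fitting
    cost one triangular solve per query batch.
    """

    hyperparams: GPHyperparams
    train_points: np.ndarray
    train_values: np.ndarray          # standardized
    y_mean: float
    y_sd: float
    kernel_kind: str = "matern52"
    warnings_log: tuple[str, ...] = ()
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def n_train(self) -> int:
        return len(self.train_values)

    def to_json(self) -> str:
        return json.dumps({
            "hyperparams": {
                "lengthscales": list(self.hyperparams.lengthscales),
                "signal_variance": self.hyperparams.signal_variance,
                "noise_variance": self.hyperparams.noise_variance,
                "constant_mean": self.hyperparams.constant_mean,
            },
            "standardization": {"y_mean": self.y_mean, "y_sd": self.y_sd},
            "kernel": self.kernel_kind,
            "train_points": self.train_points.tolist(),
            "train_values": self.train_values.tolist(),
            "warnings": list(self.warnings_log),
        }, indent=2)


def _solve_model(hp: GPHyperparams, X: np.ndarray, y_std: np.ndarray,
                 y_mean: float, y_sd: float, kind: str,
                 warn: Sequence[str] = ()) -> GPModel:
    K = kernel_matrix(X, X, hp, kind)
    L, _ = _chol_with_jitter(K, hp.noise_variance)
    alpha = linalg.cho_solve((L, True), y_std - hp.constant_mean)
    return GPModel(hyperparams=hp, train_points=X, train_values=y_std,
                   y_mean=y_mean, y_sd=y_sd, kernel_kind=kind,
                   warnings_log=tuple(warn), _chol=L, _alpha=alpha)


def _default_hyperparams(d: int) -> GPHyperparams:
    # prior guess: lengthscale ~ a third of the cube edge, unit signal,
    # small-but-nonzero noise
    return GPHyperparams(lengthscales=(0.3,) * d, signal_variance=1.0,
                         noise_variance=1e-2)


def observations_to_arrays(observations: Sequence[Observation],
                           space: DesignSpace) -> tuple[np.ndarray, np.ndarray]:
    """Stack observations into (unit-coordinate X, replicate-mean y)."""
    levels = np.array([obs.point.coords for obs in observations], dtype=float)
    X = levels_to_unit(levels, space)
    y = np.array([obs.mean_value for obs in observations], dtype=float)
    return X, y


def fit_gp(observations: Sequence[Observation], space: DesignSpace,
           fit_config: FitConfig = FitConfig()) -> GPModel:
    """Fit the surrogate to replicate-mean observations by multi-start MML.

    Repeated observations of the same point (the control construct rebuilt
    every round) are kept as separate rows; the noise term reconciles them.
    Below a floor of ``2 d`` observations the prior-default hyperparameters
    are used without optimization (too little data to estimate lengthscales).
    """
    if len(observations) < 1:
        raise ValidationError("need at least one observation to fit")
    X, y = observations_to_arrays(observations, space)
    return fit_gp_arrays(X, y, fit_config)


def fit_gp_arrays(X: np.ndarray, y: np.ndarray,
                  fit_config: FitConfig = FitConfig()) -> GPModel:
    """Array-level fit: rows of X in unit coordinates, y raw outputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    y_mean = float(y.mean())
    y_sd = float(y.std())
    warn: list[str] = []
    if y_sd < 1e-12:
        # degenerate: all outputs identical; posterior mean == the constant
        warn.append("all observed values identical; using prior-default fit")
        y_sd = 1.0
        y_std = y - y_mean
        return _solve_model(_default_hyperparams(d), X, y_std, y_mean, y_sd,
                            fit_config.kernel, warn)
    y_std = (y - y_mean) / y_sd

    if n < 2 * d:
        warn.append(f"only {n} observations (< 2d = {2 * d}); "
                    "prior-default hyperparameters, no optimization")
        return _solve_model(_default_hyperparams(d), X, y_std, y_mean, y_sd,
                            fit_config.kernel, warn)

    lb = np.log(np.array(
        [fit_config.lengthscale_bounds[0]] * d
        + [fit_config.signal_bounds[0], fit_config.noise_bounds[0]]
    ))
    ub = np.log(np.array(
        [fit_config.lengthscale_bounds[1]] * d
        + [fit_config.signal_bounds[1], fit_config.noise_bounds[1]]
    ))
    bounds = list(zip(lb, ub))
    rng = np.random.default_rng(fit_config.seed)

    starts = [np.log(np.array([0.3] * d + [1.0, 1e-2]))]
    if fit_config.warm_start is not None:
        ws = fit_config.warm_start
        starts.append(np.log(np.clip(
            np.array(list(ws.lengthscales) + [ws.signal_variance,
                                              max(ws.noise_variance, 1e-8)]),
            np.exp(lb), np.exp(ub))))
    for _ in range(fit_config.restarts):
        starts.append(rng.uniform(lb, ub))

    best_theta, best_nll = None, np.inf
    n_failed = 0
    for th0 in starts:
        res = optimize.minimize(
            _lml_and_grad, np.clip(th0, lb, ub),
            args=(X, y_std, fit_config.kernel),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200},
        )
        if not res.success:
            n_failed += 1
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_theta = res.fun, res.x
    if best_theta is None:
        warn.append("all optimizer restarts failed; falling back to prior defaults")
        warnings.warn(warn[-1], RuntimeWarning, stacklevel=2)
        return _solve_model(_default_hyperparams(d), X, y_std, y_mean, y_sd,
                            fit_config.kernel, warn)
    if n_failed == len(starts):
        warn.append("optimizer did not converge on any restart; "
                    "using best evaluated candidate")

    hp = GPHyperparams(
        lengthscales=tuple(np.exp(best_theta[:d])),
        signal_variance=float(np.exp(best_theta[d])),
        # keep a floor so the posterior never claims exact knowledge
        noise_variance=float(max(np.exp(best_theta[d + 1]), 1e-8)),
        constant_mean=0.0,
    )
    return _solve_model(hp, X, y_std, y_mean, y_sd, fit_config.kernel, warn)


def posterior(model: GPModel, query_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive means and variances at unit-coordinate query rows.

    De-standardized: means on the original output scale, variances scaled by
    ``y_sd**2``.  Batched over the full grid in one call.
    """
    if model._chol is None or model._alpha is None:
        raise RuntimeError("model is not fitted; no solved state available")
    Xq = np.atleast_2d(np.asarray(query_points, dtype=float))
    hp = model.hyperparams
    Ks = kernel_matrix(Xq, model.train_points, hp, model.kernel_kind)  # (m, n)
    mean_std = hp.constant_mean + Ks @ model._alpha
    V = linalg.solve_triangular(model._chol, Ks.T, lower=True)  # (n, m)
    var_std = hp.signal_variance - (V**2).sum(axis=0)
    var_std = np.maximum(var_std, 0.0)
    means = model.y_mean + model.y_sd * mean_std
    variances = (model.y_sd**2) * var_std
    return means, variances


def augment_model(model: GPModel, new_points: np.ndarray,
                  new_values_raw: np.ndarray) -> GPModel:
    """Add observations with hyperparameters and standardization frozen.

    Used for fantasy updates inside a batch: the Gram factor is recomputed
    but neither theta nor (y_mean, y_sd) move.
    """
    Xn = np.vstack([model.train_points, np.atleast_2d(new_points)])
    new_std = (np.asarray(new_values_raw, dtype=float) - model.y_mean) / model.y_sd
    yn = np.concatenate([model.train_values, np.atleast_1d(new_std)])
    return _solve_model(model.hyperparams, Xn, yn, model.y_mean, model.y_sd,
                        model.kernel_kind, model.warnings_log)
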