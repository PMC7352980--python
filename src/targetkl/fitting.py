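"""Parametric fits of similarity distributions.

Two estimators turn similarity samples into the distributions that the
divergence stage compares:

* :func:`fit_gmm_em` — a K-component univariate Gaussian mixture fitted by
  expectation-maximization, used for a target class's representative
  ("Q") distribution of intra-class ligand-pair similarities.  The mixture
  accommodates the right-skewed, non-Gaussian shapes real classes show.
* :func:`fit_gaussian_ml` — a single-Gaussian maximum-likelihood fit
  (sample mean, divide-by-n standard deviation), used for each query's
  similarity vector, which is assumed unimodal.

Gaussians are fitted on the whole real line even though similarities live
in a bounded score range; the fitted distributions sit well inside the
range in practice, and the downstream divergences are taken between the
untruncated forms.

EM is run to a log-likelihood-increment tolerance with multiple restarts
(one deterministic quantile-spread initialization plus seeded random
restarts), keeping the best local optimum.  The per-iteration
log-likelihood trace is returned and is non-decreasing, the standard EM
guarantee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .density import HistogramDensity
from .simdata import EmptyDataError, MatrixValidationError

__all__ = [
    "GaussianParams",
    "GMMParams",
    "EMConfig",
    "EMTrace",
    "fit_gaussian_ml",
    "fit_gaussian_ml_binned",
    "fit_gmm_em",
    "gmm_pdf",
    "gmm_logpdf",
    "gmm_loglik",
    "save_gmm",
    "load_gmm",
]

DEFAULT_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GaussianParams:
    """Single-Gaussian parameters (mu, sigma) of one query's similarities."""

    mu: float
    sigma: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise MatrixValidationError("Gaussian parameters must be finite")
        if self.sigma <= 0:
            raise MatrixValidationError(f"sigma must be positive, got {self.sigma}")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return norm.pdf(x, loc=self.mu, scale=self.sigma)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return norm.logpdf(x, loc=self.mu, scale=self.sigma)


@dataclass(frozen=True)
class GMMParams:
    """K-component Gaussian-mixture parameters of a class's Q-distribution.

    Components are stored sorted by mean (canonical order), weights sum to
    one, and every standard deviation is positive.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float).ravel()
        m = np.asarray(self.means, float).ravel()
        s = np.asarray(self.sds, float).ravel()
        if not (w.size == m.size == s.size) or w.size == 0:
            raise MatrixValidationError("weights/means/sds must match and be non-empty")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise MatrixValidationError("weights must be non-negative and sum to 1")
        if np.any(s <= 0):
            raise MatrixValidationError("all component sds must be positive")
        order = np.argsort(m, kind="stable")
        object.__setattr__(self, "weights", w[order])
        object.__setattr__(self, "means", m[order])
        object.__setattr__(self, "sds", s[order])

    @property
    def K(self) -> int:
        return self.weights.size

    def mean(self) -> float:
        """Mixture mean."""
        return float(np.sum(self.weights * self.means))

    def sd(self) -> float:
        """Mixture standard deviation."""
        mu = self.mean()
        second = np.sum(self.weights * (self.sds**2 + self.means**2))
        return float(np.sqrt(second - mu**2))

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return gmm_pdf(self, x)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return gmm_logpdf(self, x)

    @classmethod
    def single(cls, g: GaussianParams) -> "GMMParams":
        return cls(weights=np.array([1.0]), means=np.array([g.mu]), sds=np.array([g.sigma]))

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "weights": [float(v) for v in self.weights],
            "means": [float(v) for v in self.means],
            "sds": [float(v) for v in self.sds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMMParams":
        return cls(
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
        )


@dataclass(frozen=True)
class EMConfig:
    """EM algorithm settings.

    ``tol`` is the stopping threshold on the log-likelihood increment;
    ``n_restarts`` counts total initializations (one deterministic
    quantile-spread start plus seeded random restarts); ``sigma_floor``
    bounds component standard deviations away from zero to prevent
    likelihood blow-up on collapsed components.
    """

    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    init: str = "quantile"
    n_restarts: int = 5
    sigma_floor: float = DEFAULT_SIGMA_FLOOR

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise MatrixValidationError("tol must be positive")
        if self.max_iter < 1:
            raise MatrixValidationError("max_iter must be at least 1")
        if self.n_restarts < 1:
            raise MatrixValidationError("n_restarts must be at least 1")


@dataclass
class EMTrace:
    """Per-run diagnostics: log-likelihood path and convergence flags."""

    loglik: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    flags: list[str] = field(default_factory=list)
    best_restart: int = 0


def fit_gaussian_ml(
    values: np.ndarray, sigma_floor: float = DEFAULT_SIGMA_FLOOR
) -> GaussianParams:
    """Maximum-likelihood Gaussian fit of a raw similarity vector.

    The MLE for a normal sample is the sample mean and the divide-by-n
    standard deviation.  A zero-variance (constant) sample yields
    ``sigma = sigma_floor`` with the ``degenerate`` flag set.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise EmptyDataError("Gaussian ML fit needs at least 2 values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma < sigma_floor:
        return GaussianParams(mu=mu, sigma=sigma_floor, degenerate=True)
    return GaussianParams(mu=mu, sigma=sigma)


def fit_gaussian_ml_binned(
    density: HistogramDensity, sigma_floor: float = DEFAULT_SIGMA_FLOOR
) -> GaussianParams:
    """Gaussian ML fit of a binned density (bin midpoints weighted by mass).

    Variant reproducing a pipeline where queries are histogrammed before
    fitting; it differs from the raw fit by at most the binning error
    (of order one bin width).
    """
    mu = density.mean()
    sigma = density.sd()
    if sigma < sigma_floor:
        return GaussianParams(mu=mu, sigma=sigma_floor, degenerate=True)
    return GaussianParams(mu=mu, sigma=sigma)


def gmm_pdf(params: GMMParams, x: np.ndarray) -> np.ndarray:
    """Mixture density: weighted sum of component Gaussian densities."""
    x = np.asarray(x, dtype=float)
    comp = norm.pdf(x[..., None], loc=params.means, scale=params.sds)
    return comp @ params.weights


def gmm_logpdf(params: GMMParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lp = norm.logpdf(x[..., None], loc=params.means, scale=params.sds)
    with np.errstate(divide="ignore"):  # zero-weight components -> -inf, fine
        logw = np.log(params.weights)
    return logsumexp(lp + logw, axis=-1)


def gmm_loglik(params: GMMParams, values: np.ndarray) -> float:
    return float(np.sum(gmm_logpdf(params, np.asarray(values, float).ravel())))


def _init_means(
    values: np.ndarray, K: int, restart: int, rng: np.random.Generator, init: str
) -> np.ndarray:
    if restart == 0 and init == "quantile":
        qs = (np.arange(K) + 1.0) / (K + 1.0)
        return np.quantile(values, qs)
    return rng.choice(values, size=K, replace=values.size < K)


def _em_single_run(
    values: np.ndarray,
    K: int,
    init_means: np.ndarray,
    config: EMConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, EMTrace]:
    n = values.size
    weights = np.full(K, 1.0 / K)
    means = init_means.astype(float).copy()
    pooled = max(float(values.std(ddof=0)), config.sigma_floor)
    sds = np.full(K, pooled)
    trace = EMTrace()
    prev_ll = -np.inf
    x = values[:, None]
    for it in range(config.max_iter):
        # E-step in log space: responsibilities and observed-data loglik
        log_joint = np.log(weights) + norm.logpdf(x, loc=means, scale=sds)
        log_norm = logsumexp(log_joint, axis=1, keepdims=True)
        ll = float(log_norm.sum())
        trace.loglik.append(ll)
        trace.n_iter = it + 1
        if it > 0 and ll - prev_ll < config.tol:
            trace.converged = True
            break
        prev_ll = ll
        resp = np.exp(log_joint - log_norm)
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            trace.flags.append("empty-component")
            nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x).sum(axis=0) / nk
        var = (resp * (x - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < config.sigma_floor):
            trace.flags.append("sigma-floored")
            sds = np.maximum(sds, config.sigma_floor)
    if not trace.converged:
        trace.flags.append("max-iter-reached")
    return weights, means, sds, trace


def fit_gmm_em(
    values: np.ndarray, K: int, config: EMConfig | None = None
) -> tuple[GMMParams, EMTrace]:
    """Fit a K-component univariate Gaussian mixture by EM.

    Runs ``config.n_restarts`` initializations (the first deterministic,
    the rest seeded random draws of component centers from the data) and
    returns the parameters with the highest final log-likelihood together
    with that run's trace.  For ``K=1`` the first M-step already lands on
    the closed-form ML solution, so the result matches
    :func:`fit_gaussian_ml` to machine precision.
    """
    if config is None:
        config = EMConfig()
    values = np.asarray(values, dtype=float).ravel()
    if K < 1:
        raise MatrixValidationError("K must be at least 1")
    if values.size < K:
        raise EmptyDataError(
            f"need at least K={K} values to fit a {K}-component mixture, "
            f"got {values.size}"
        )
    rng = np.random.default_rng(config.seed)
    n_restarts = 1 if K == 1 else config.n_restarts
    best: tuple[float, GMMParams, EMTrace] | None = None
    for restart in range(n_restarts):
        init = _init_means(values, K, restart, rng, config.init)
        weights, means, sds, trace = _em_single_run(values, K, init, config)
        trace.best_restart = restart
        params = GMMParams(weights=weights, means=means, sds=sds)
        final_ll = trace.loglik[-1]
        if best is None or final_ll > best[0]:
            best = (final_ll, params, trace)
    assert best is not None
    return best[1], best[2]


def save_gmm(
    params: GMMParams,
    path: str | Path,
    trace: EMTrace | None = None,
    extra: dict | None = None,
) -> None:
    """Serialize a fitted mixture (and fit diagnostics) to JSON."""
    payload = params.to_dict()
    if trace is not None:
        payload.update(
            loglik=float(trace.loglik[-1]),
            converged=bool(trace.converged),
            n_iter=int(trace.n_iter),
            flags=list(trace.flags),
        )
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_gmm(path: str | Path) -> GMMParams:
    with open(path) as fh:
        return GMMParams.from_dict(json.load(fh))
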