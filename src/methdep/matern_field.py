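"""Parameterization and covariance mathematics of the 1-D Matern Gaussian field.

Methylation residuals along a chromosome are modeled as a stationary
Gaussian random field on base-pair coordinates with a Matern covariance.
The smoothness is fixed at ``lambda = 0.5`` throughout the pipeline, which
gives exponential decay ``sigma^2 * exp(-kappa * d)`` — the Ornstein-
Uhlenbeck case — and admits an exact Markov (tridiagonal-precision)
representation on arbitrary irregular 1-D positions.  General smoothness is
supported by :func:`matern_covariance` for testing only.

Parameter conventions
---------------------
kappa : inverse base pairs
    Decay rate of the correlation.  Interpreted through the range
    ``r = sqrt(8*lambda)/kappa``, the distance at which the correlation
    has fallen to roughly 0.1.
tau : dimensionless
    Precision-like scale.  The marginal variance of the field follows the
    1-D convention ``sigma^2 = Gamma(l) / (Gamma(l+1/2) * sqrt(4*pi)
    * kappa^(2l) * tau^2)``, which for ``l = 0.5`` reduces to
    ``sigma^2 = 1 / (2*kappa*tau^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma
from scipy.special import kv as _bessel_kv

__all__ = [
    "MaternSpec",
    "HyperPriors",
    "matern_covariance",
    "range_from_kappa",
    "kappa_from_range",
    "sigma_from_tau_kappa",
    "tau_from_sigma_kappa",
    "default_priors",
    "markov_precision",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class MaternSpec:
    """Dependency parameterization (lambda, kappa, tau) of the latent field.

    ``range_r`` and ``sigma`` are derived on construction and always
    consistent with (lambda, kappa, tau).
    """

    kappa: float
    tau: float
    lambda_smoothness: float = 0.5
    range_r: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        _check_positive(
            kappa=self.kappa, tau=self.tau, lambda_smoothness=self.lambda_smoothness
        )
        object.__setattr__(
            self, "range_r", range_from_kappa(self.kappa, self.lambda_smoothness)
        )
        object.__setattr__(
            self,
            "sigma",
            sigma_from_tau_kappa(self.tau, self.kappa, self.lambda_smoothness),
        )

    @property
    def sigma2(self) -> float:
        """Marginal variance of the latent field."""
        return self.sigma**2

    @classmethod
    def from_range_sigma(
        cls, range_r: float, sigma: float, lambda_smoothness: float = 0.5
    ) -> "MaternSpec":
        """Build a spec from the interpretable (range, marginal sd) pair."""
        _check_positive(range_r=range_r, sigma=sigma)
        kappa = kappa_from_range(range_r, lambda_smoothness)
        tau = tau_from_sigma_kappa(sigma, kappa, lambda_smoothness)
        return cls(kappa=kappa, tau=tau, lambda_smoothness=lambda_smoothness)


@dataclass(frozen=True)
class HyperPriors:
    """Priors of the per-track Bayesian model.

    Gaussian priors on the intercept and on log tau / log kappa, and a
    Gamma prior on the noise precision 1/sigma0^2.  The defaults are the
    standard vague settings: N(0, 1e6) intercept, Gamma(1, 5e-5) noise
    precision, and log-scale Gaussians with precision 0.05 (variance 20)
    on the dependency parameters.
    """

    beta_mean: float = 0.0
    beta_variance: float = 1e6
    noise_precision_shape: float = 1.0
    noise_precision_rate: float = 0.00005
    logtau_mean: float = math.log(math.sqrt(750.0))
    logtau_precision: float = 0.05
    logkappa_mean: float = math.log(2.0 / 3000.0)
    logkappa_precision: float = 0.05

    def __post_init__(self) -> None:
        _check_positive(
            beta_variance=self.beta_variance,
            noise_precision_shape=self.noise_precision_shape,
            noise_precision_rate=self.noise_precision_rate,
            logtau_precision=self.logtau_precision,
            logkappa_precision=self.logkappa_precision,
        )

    @property
    def logtau_sd(self) -> float:
        return self.logtau_precision**-0.5

    @property
    def logkappa_sd(self) -> float:
        return self.logkappa_precision**-0.5


def range_from_kappa(kappa: float, lambda_smoothness: float = 0.5) -> float:
    """Range r = sqrt(8*lambda)/kappa, the distance of ~0.1 correlation."""
    _check_positive(kappa=kappa, lambda_smoothness=lambda_smoothness)
    return math.sqrt(8.0 * lambda_smoothness) / kappa


def kappa_from_range(range_r: float, lambda_smoothness: float = 0.5) -> float:
    """Inverse of :func:`range_from_kappa`."""
    _check_positive(range_r=range_r, lambda_smoothness=lambda_smoothness)
    return math.sqrt(8.0 * lambda_smoothness) / range_r


def sigma_from_tau_kappa(
    tau: float, kappa: float, lambda_smoothness: float = 0.5
) -> float:
    """Marginal standard deviation of the field from (tau, kappa).

    Uses the 1-D convention
    ``sigma^2 = Gamma(l) / (Gamma(l + 1/2) * sqrt(4*pi) * kappa^(2l) * tau^2)``.
    """
    _check_positive(tau=tau, kappa=kappa, lambda_smoothness=lambda_smoothness)
    l = lambda_smoothness
    sigma2 = _gamma(l) / (
        _gamma(l + 0.5) * math.sqrt(4.0 * math.pi) * kappa ** (2.0 * l) * tau**2
    )
    return math.sqrt(sigma2)


def tau_from_sigma_kappa(
    sigma: float, kappa: float, lambda_smoothness: float = 0.5
) -> float:
    """Inverse of :func:`sigma_from_tau_kappa` (exact round-trip)."""
    _check_positive(sigma=sigma, kappa=kappa, lambda_smoothness=lambda_smoothness)
    l = lambda_smoothness
    tau2 = _gamma(l) / (
        _gamma(l + 0.5) * math.sqrt(4.0 * math.pi) * kappa ** (2.0 * l) * sigma**2
    )
    return math.sqrt(tau2)


def matern_covariance(distance_bp, spec: MaternSpec):
    """Matern covariance at one or more base-pair distances.

    ``sigma^2 / (Gamma(l) 2^(l-1)) * (kappa*d)^l * K_l(kappa*d)`` for d > 0
    and ``sigma^2`` at d = 0.  For l = 0.5 this equals
    ``sigma^2 * exp(-kappa*d)``.
    """
    d = np.asarray(distance_bp, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_bp must be non-negative")
    l = spec.lambda_smoothness
    sigma2 = spec.sigma2
    scaled = spec.kappa * d
    with np.errstate(invalid="ignore"):
        cov = (
            sigma2
            / (_gamma(l) * 2.0 ** (l - 1.0))
            * scaled**l
            * _bessel_kv(l, scaled)
        )
    cov = np.where(d == 0.0, sigma2, cov)
    if np.ndim(distance_bp) == 0:
        return float(cov)
    return cov


def default_priors(
    range0: float = 3000.0,
    sigma2_0: float = 1.0,
    lambda_smoothness: float = 0.5,
    beta_mean: float = 0.0,
    beta_variance: float = 1e6,
    noise_precision_shape: float = 1.0,
    noise_precision_rate: float = 0.00005,
    log_precision: float = 0.05,
) -> HyperPriors:
    """Prior means for (log tau, log kappa) calibrated from an a-priori range
    and marginal variance.

    With the defaults range0 = 3000 bp and sigma2_0 = 1 this gives
    kappa_m = 2/3000 ~ 0.00067 and tau_m = sqrt(750) ~ 27.39.
    """
    _check_positive(range0=range0, sigma2_0=sigma2_0)
    kappa_m = kappa_from_range(range0, lambda_smoothness)
    tau_m = tau_from_sigma_kappa(math.sqrt(sigma2_0), kappa_m, lambda_smoothness)
    return HyperPriors(
        beta_mean=beta_mean,
        beta_variance=beta_variance,
        noise_precision_shape=noise_precision_shape,
        noise_precision_rate=noise_precision_rate,
        logtau_mean=math.log(tau_m),
        logtau_precision=log_precision,
        logkappa_mean=math.log(kappa_m),
        logkappa_precision=log_precision,
    )


def _validate_positions(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 1 or pos.size < 1:
        raise ValueError("positions must be a 1-D array of length >= 1")
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        if np.any(np.diff(pos) == 0):
            raise ValueError(
                "duplicate positions detected; deduplicate or jitter explicitly "
                "(the covariance matrix would be singular)"
            )
        raise ValueError("positions must be strictly increasing")
    return pos


def markov_precision(positions, spec: MaternSpec):
    """Tridiagonal precision of the exponential field at irregular positions.

    The lambda = 0.5 field is a Markov (Ornstein-Uhlenbeck) process, so its
    precision matrix is tridiagonal with entries driven by the lag
    correlations ``rho_i = exp(-kappa * (p_{i+1} - p_i))``.  Returns
    ``(diag, offdiag, logdet)`` where ``diag`` has length n, ``offdiag``
    length n-1, and ``logdet`` is the log-determinant of the precision,
    computable in closed form:
    ``-n log sigma^2 - sum log(1 - rho_i^2)``.

    The inverse of this matrix is exactly ``sigma^2 * exp(-kappa |p_i - p_j|)``.
    """
    if spec.lambda_smoothness != 0.5:
        raise ValueError(
            "the Markov representation exists only for lambda = 0.5 "
            f"(got {spec.lambda_smoothness})"
        )
    pos = _validate_positions(positions)
    n = pos.size
    sigma2 = spec.sigma2
    if n == 1:
        return np.array([1.0 / sigma2]), np.zeros(0), -math.log(sigma2)
    rho = np.exp(-spec.kappa * np.diff(pos))
    one_m_r2 = 1.0 - rho**2
    # diag_i = 1 + rho_i^2/(1-rho_i^2) + rho_{i-1}^2/(1-rho_{i-1}^2)
    diag = np.ones(n)
    diag[:-1] += rho**2 / one_m_r2
    diag[1:] += rho**2 / one_m_r2
    offdiag = -rho / one_m_r2
    diag /= sigma2
    offdiag /= sigma2
    logdet = -n * math.log(sigma2) - float(np.sum(np.log(one_m_r2)))
    return diag, offdiag, logdet


def markov_precision_dense(positions, spec: MaternSpec) -> np.ndarray:
    """Dense n x n matrix form of :func:`markov_precision` (for small n)."""
    diag, off, _ = markov_precision(positions, spec)
    q = np.diag(diag)
    n = diag.size
    idx = np.arange(n - 1)
    q[idx, idx + 1] = off
    q[idx + 1, idx] = off
    return q
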