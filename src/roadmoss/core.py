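"""Domain types and the mathematical core of the geostatistical model.

The model describes element concentrations ``y_ij`` (mg/kg dry weight) in
moss tissue at site ``i``, replicate ``j``, on the natural-log scale:

    log(y_ij) = x_i' beta + alpha_i + eta_i + eps_ij

with ``x_i = (1, log d_i, south_i, log d_i * south_i)`` built from distance to
the road and side of the road, independent site effects
``alpha_i ~ N(0, sigma1_sq)``, a spatial random field
``eta ~ N(0, Sigma)`` with exponential covariance
``Sigma[i, i~] = sigma2_sq * exp(-d_{ii~} / theta)``, and measurement error
``eps_ij ~ N(0, sigma0_sq)``.

Priors (weakly informative): ``beta ~ N(0, 100 I)``; Gamma(2, 2) (shape-rate)
on each of the three variances; Half-Normal with scale 5000 m on the spatial
range ``theta``.

Everything here is pure computation on plain records and numpy arrays; the
sampling, prediction and summary layers build on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import gamma as gamma_dist
from scipy.stats import halfnorm

__all__ = [
    "SiteRecord",
    "Observation",
    "ModelParameters",
    "LatentState",
    "SIDES",
    "ELEMENTS",
    "YEARS",
    "make_predictor_vector",
    "design_matrix",
    "pairwise_distances",
    "exponential_covariance",
    "log_joint_density",
    "site_index_of_observations",
]

SIDES = ("north", "south")
ELEMENTS = ("Zn", "Pb", "Cd")
YEARS = (2006, 2017)

#: Relative jitter added to the diagonal of the spatial covariance before
#: factorization.  Autocorrelation plots 10-20 m apart make Sigma nearly
#: singular without it.
SPATIAL_JITTER = 1e-8


@dataclass(frozen=True)
class SiteRecord:
    """A sampled location: planar coordinates (m), distance to road, side."""

    site_id: str
    easting: float
    northing: float
    distance_to_road: float
    side: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.distance_to_road) or self.distance_to_road <= 0:
            raise ValueError(
                f"site {self.site_id!r}: distance_to_road must be strictly "
                f"positive (got {self.distance_to_road!r}); the model uses "
                "log-distance"
            )
        if self.side not in SIDES:
            raise ValueError(f"site {self.site_id!r}: side must be one of {SIDES}")


@dataclass(frozen=True)
class Observation:
    """One tissue measurement: element, year, replicate, concentration mg/kg."""

    site_id: str
    element: str
    year: int
    replicate_index: int
    concentration: float

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}; expected {ELEMENTS}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise ValueError(
                f"observation at site {self.site_id!r}: concentration must be "
                f"strictly positive (got {self.concentration!r}); the model "
                "operates on the log scale"
            )


@dataclass
class ModelParameters:
    """beta (intercept, log-distance, south, interaction) and the covariance
    parameters: nugget ``sigma0_sq``, site-effect variance ``sigma1_sq``,
    partial sill ``sigma2_sq``, range ``theta`` (m)."""

    beta: np.ndarray
    sigma0_sq: float
    sigma1_sq: float
    sigma2_sq: float
    theta: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must be a 4-vector")
        for name in ("sigma0_sq", "sigma1_sq", "sigma2_sq", "theta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive (got {v!r})")


@dataclass
class LatentState:
    """Per-site latent values: site effects ``alpha`` and spatial field ``eta``."""

    alpha: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.alpha.shape != self.eta.shape or self.alpha.ndim != 1:
            raise ValueError("alpha and eta must be 1-d arrays of equal length")


def make_predictor_vector(distance_m: float, side: str) -> np.ndarray:
    """Design vector (1, ln d, I_south, ln d * I_south) for one location."""
    if not np.isfinite(distance_m) or distance_m <= 0:
        raise ValueError(f"distance must be strictly positive (got {distance_m!r})")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES} (got {side!r})")
    log_d = np.log(distance_m)
    south = 1.0 if side == "south" else 0.0
    return np.array([1.0, log_d, south, log_d * south])


def design_matrix(sites: list[SiteRecord]) -> np.ndarray:
    """(n, 4) design matrix over sites, rows in site order."""
    return np.array([make_predictor_vector(s.distance_to_road, s.side) for s in sites])


def pairwise_distances(sites: list[SiteRecord]) -> np.ndarray:
    """Euclidean pairwise distances (m) on the projected planar coordinates."""
    xy = np.array([[s.easting, s.northing] for s in sites])
    return cdist(xy, xy)


def exponential_covariance(
    pairwise_dist: np.ndarray, sigma2_sq: float, theta: float
) -> np.ndarray:
    """Exponential covariance sigma2_sq * exp(-d/theta) over a distance matrix.

    The input must be a symmetric, non-negative matrix with zero diagonal.
    The result is symmetric positive semidefinite (the exponential kernel is
    valid in the plane).
    """
    d = np.asarray(pairwise_dist, dtype=float)
    if sigma2_sq <= 0 or theta <= 0:
        raise ValueError("sigma2_sq and theta must be strictly positive")
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("pairwise distance matrix must be square")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T, rtol=0, atol=1e-8):
        raise ValueError("pairwise distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-8):
        raise ValueError("pairwise distance matrix must have a zero diagonal")
    return sigma2_sq * np.exp(-d / theta)


def site_index_of_observations(
    observations: list[Observation], sites: list[SiteRecord]
) -> np.ndarray:
    """Index into ``sites`` for each observation; errors on unknown sites."""
    lookup = {s.site_id: i for i, s in enumerate(sites)}
    if len(lookup) != len(sites):
        raise ValueError("duplicate site_id in sites")
    try:
        return np.array([lookup[o.site_id] for o in observations], dtype=int)
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"observation references unknown site {exc.args[0]!r}") from exc


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, var: float) -> float:
    x = np.atleast_1d(x)
    resid = x - mean
    return float(-0.5 * x.size * np.log(2 * np.pi * var) - 0.5 * np.sum(resid**2) / var)


def _mvn_logpdf_chol(x: np.ndarray, cov: np.ndarray) -> float:
    jitter = SPATIAL_JITTER * np.max(np.diag(cov))
    L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
    w = np.linalg.solve(L, x)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (x.size * np.log(2 * np.pi) + logdet + w @ w))


def log_joint_density(
    params: ModelParameters,
    latent: LatentState,
    observations: list[Observation],
    sites: list[SiteRecord],
) -> float:
    """Joint log-density of data, latent effects and priors.

    Sum of (a) the Normal log-density of each ``log y_ij`` around
    ``x_i' beta + alpha_i + eta_i`` with variance ``sigma0_sq``; (b) the
    ``N(0, sigma1_sq)`` density of each ``alpha_i`` and the joint
    ``N(0, Sigma)`` density of ``eta``; and (c) the prior densities of
    ``beta``, the three variances and ``theta``.
    """
    n = len(sites)
    if latent.alpha.shape != (n,):
        raise ValueError("latent state must have one (alpha, eta) pair per site")
    X = design_matrix(sites)
    idx = site_index_of_observations(observations, sites)
    y = np.array([o.concentration for o in observations])
    if y.size and np.any(y <= 0):
        raise ValueError("concentrations must be strictly positive")

    mu_site = X @ params.beta + latent.alpha + latent.eta
    data_term = _normal_logpdf(np.log(y), mu_site[idx], params.sigma0_sq) if y.size else 0.0

    alpha_term = _normal_logpdf(latent.alpha, 0.0, params.sigma1_sq)
    Sigma = exponential_covariance(pairwise_distances(sites), params.sigma2_sq, params.theta)
    eta_term = _mvn_logpdf_chol(latent.eta, Sigma)

    prior = _normal_logpdf(params.beta, 0.0, 100.0)
    for v in (params.sigma0_sq, params.sigma1_sq, params.sigma2_sq):
        prior += float(gamma_dist.logpdf(v, a=2.0, scale=0.5))
    prior += float(halfnorm.logpdf(params.theta, scale=5000.0))

    return data_term + alpha_term + eta_term + prior
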