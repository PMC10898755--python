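"""Posterior-predictive concentrations at prediction-grid locations.

For each of K parent posterior draws (sampled without replacement from the
retained draws), the spatial field at the grid is drawn from its exact
Gaussian conditional given that draw's field values at the modeled sites and
its (partial sill, range).  The conditional draw is joint across all grid
points — spatially coherent — computed by blocked Cholesky factorization of
the joint site+grid covariance: each block of <= 512 grid points is
conditioned on the sites and on all previously drawn blocks, which is
algebraically identical to one full joint factorization, so the block
partition does not change the result (beyond floating-point roundoff).

Concentration draws on the original scale are

    yhat^(k)_l = exp(x_l' beta^(k) + eta*^(k)_l + alpha*^(k)_l)

where a fresh site effect ``alpha* ~ N(0, sigma1_sq^(k))`` per grid point
represents prediction at a new, unsampled site (on by default; switchable),
and measurement error is never added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist

from .core import SPATIAL_JITTER, SiteRecord, make_predictor_vector
from .inference import PosteriorDrawSet
from .synthetic import GridPoint

__all__ = [
    "ConditionalFieldDraws",
    "PredictiveDrawSet",
    "kriging_conditional_moments",
    "conditional_spatial_draws",
    "predictive_concentration_draws",
    "pointwise_map_summaries",
]

DEFAULT_K = 200
BLOCK_SIZE = 512


@dataclass
class ConditionalFieldDraws:
    """Joint conditional draws of the spatial field at the grid.

    ``values`` is (K, m); ``parent_indices`` points back into the posterior
    draw set so downstream stages use the same K parent draws.
    """

    values: np.ndarray
    parent_indices: np.ndarray


@dataclass
class PredictiveDrawSet:
    """Original-scale concentration draws (K, m) over grid points."""

    values: np.ndarray
    parent_indices: np.ndarray
    grid_ids: list[str]
    element: str | None = None
    year: int | None = None

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("predictive concentration draws must be positive")


def _robust_cholesky(S: np.ndarray, scale: float) -> np.ndarray:
    """Cholesky with escalating diagonal jitter; conditional covariances at
    grid points coincident with sites are singular up to roundoff."""
    jit = SPATIAL_JITTER * scale
    for _ in range(8):
        try:
            return np.linalg.cholesky(S + jit * np.eye(S.shape[0]))
        except np.linalg.LinAlgError:
            jit *= 100.0
    raise np.linalg.LinAlgError("conditional covariance is not positive definite")


def kriging_conditional_moments(
    site_xy: np.ndarray,
    grid_xy: np.ndarray,
    eta: np.ndarray,
    sigma2_sq: float,
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian conditional mean and covariance of the field at the
    grid given its values at the sites (simple kriging with the exponential
    covariance; the usual diagonal jitter is included on the site block)."""
    site_xy = np.asarray(site_xy, float)
    grid_xy = np.asarray(grid_xy, float)
    C_ss = sigma2_sq * np.exp(-cdist(site_xy, site_xy) / theta) \
        + SPATIAL_JITTER * sigma2_sq * np.eye(len(site_xy))
    C_gs = sigma2_sq * np.exp(-cdist(grid_xy, site_xy) / theta)
    C_gg = sigma2_sq * np.exp(-cdist(grid_xy, grid_xy) / theta)
    Ls = np.linalg.cholesky(C_ss)
    W = solve_triangular(Ls, C_gs.T, lower=True)          # (n, m)
    mean = W.T @ solve_triangular(Ls, np.asarray(eta, float), lower=True)
    cov = C_gg - W.T @ W
    return mean, cov


def conditional_spatial_draws(
    drawset: PosteriorDrawSet,
    sites: list[SiteRecord],
    grid: list[GridPoint],
    K: int = DEFAULT_K,
    seed: int = 0,
    block_size: int = BLOCK_SIZE,
) -> ConditionalFieldDraws:
    """Draw the spatial field at the grid for K parent posterior draws.

    For parent draw k with field values ``eta`` at the sites and covariance
    parameters (sigma2_sq, theta), the grid field is drawn from
    ``N(S_gs S_ss^-1 eta, S_gg - S_gs S_ss^-1 S_sg)`` jointly over the grid.
    """
    if not grid:
        raise ValueError("prediction grid is empty")
    if K > drawset.n_draws:
        raise ValueError(f"K={K} exceeds the {drawset.n_draws} retained draws")
    if drawset.eta is None:
        raise ValueError("posterior draw set has no latent field draws "
                         "(fit with include_latent=True)")
    rng = np.random.default_rng(seed)
    parents = np.sort(rng.choice(drawset.n_draws, size=K, replace=False))

    site_xy = np.array([[s.easting, s.northing] for s in sites])
    grid_xy = np.array([[g.easting, g.northing] for g in grid])
    n, m = len(sites), len(grid)
    D_ss = cdist(site_xy, site_xy)
    D_gs = cdist(grid_xy, site_xy)
    D_gg = cdist(grid_xy, grid_xy)

    blocks = [np.arange(b, min(b + block_size, m)) for b in range(0, m, block_size)]
    out = np.empty((K, m))
    for k, p in enumerate(parents):
        s2 = drawset.sigma2_sq[p]
        theta = drawset.theta[p]
        eta = drawset.eta[p]
        jit = SPATIAL_JITTER * s2

        n_tot = n + m
        L = np.zeros((n_tot, n_tot))
        w = np.empty(n_tot)  # whitened conditioning values
        C_ss = s2 * np.exp(-D_ss / theta) + jit * np.eye(n)
        L[:n, :n] = np.linalg.cholesky(C_ss)
        w[:n] = solve_triangular(L[:n, :n], eta, lower=True)
        pos = n
        for gb in blocks:
            q = gb.size
            # cross-covariance of the block with sites + earlier grid points
            prev_grid = np.arange(gb[0])
            C_prev = np.concatenate(
                [s2 * np.exp(-D_gs[gb] / theta),
                 s2 * np.exp(-D_gg[np.ix_(gb, prev_grid)] / theta)], axis=1)
            T = solve_triangular(L[:pos, :pos], C_prev.T, lower=True)  # (pos, q)
            cond_mean = T.T @ w[:pos]
            C_bb = s2 * np.exp(-D_gg[np.ix_(gb, gb)] / theta) + jit * np.eye(q)
            S = C_bb - T.T @ T
            Lb = _robust_cholesky(S, s2)
            z = rng.standard_normal(q)
            out[k, gb] = cond_mean + Lb @ z
            L[pos:pos + q, :pos] = T.T
            L[pos:pos + q, pos:pos + q] = Lb
            w[pos:pos + q] = z
            pos += q
    return ConditionalFieldDraws(values=out, parent_indices=parents)


def predictive_concentration_draws(
    drawset: PosteriorDrawSet,
    grid: list[GridPoint],
    eta_star_draws: ConditionalFieldDraws,
    include_new_site_effect: bool = True,
    seed: int = 0,
) -> PredictiveDrawSet:
    """Original-scale concentration draws at the grid.

    Each draw combines the parent draw's regression surface, its conditional
    field draw, and (by default) a fresh new-site effect; measurement error
    is never included.
    """
    K, m = eta_star_draws.values.shape
    if m != len(grid):
        raise ValueError("eta-star draws are not aligned with the grid")
    parents = eta_star_draws.parent_indices
    if np.any(parents >= drawset.n_draws) or parents.size != K:
        raise ValueError("eta-star parent indices do not match the posterior draw set")
    Xg = np.array([make_predictor_vector(g.distance_to_road, g.side) for g in grid])
    log_mu = drawset.beta[parents] @ Xg.T + eta_star_draws.values  # (K, m)
    if include_new_site_effect:
        rng = np.random.default_rng(seed)
        sd = np.sqrt(drawset.sigma1_sq[parents])[:, None]
        log_mu = log_mu + sd * rng.standard_normal((K, m))
    return PredictiveDrawSet(
        values=np.exp(log_mu), parent_indices=parents,
        grid_ids=[g.grid_id for g in grid],
        element=drawset.element, year=drawset.year)


def pointwise_map_summaries(predictive: PredictiveDrawSet) -> pd.DataFrame:
    """Per-grid-point posterior mean and central 95% interval.

    Quantiles use linear interpolation of order statistics (type-7 rule).
    """
    if predictive.K < 2:
        raise ValueError("need at least 2 draws to summarize")
    v = predictive.values
    lo, hi = np.quantile(v, [0.025, 0.975], axis=0, method="linear")
    return pd.DataFrame({
        "grid_id": predictive.grid_ids,
        "mean": v.mean(axis=0),
        "q2.5": lo,
        "q97.5": hi,
    })
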