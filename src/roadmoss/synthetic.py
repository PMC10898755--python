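"""Synthetic study designs, concentration simulation and prediction grids.

The sampling design emulates a long-term moss biomonitoring network along a
haul road: 12 transects with plots at fixed distances from the road (10 m to
4 km) on both sides, a handful of roadside tissue-only points at 3 m, one
"autocorrelation" plot per transect offset 10-20 m from a far plot to inform
the spatial-range parameter, and reference sites 42-64 km south of the road.
With the default configuration the planned design yields exactly 131 tissue
samples (field duplicates included) at 110 locations.

Concentrations are simulated from the generative model in :mod:`roadmoss.core`
(log-linear distance decay, south-side effect, site effects, exponential-
covariance spatial field, lognormal measurement error), so simulated data can
drive every downstream stage — fitting, prediction and change summaries —
without any field data.

The prediction grid reproduces the five distance strata used for reporting:
1: 0-100 m, 2: 100-2,000 m, 3: 2,000-4,000 m, 4: 4,000-5,000 m and
5: 30-64 km (south side only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .core import (
    ModelParameters,
    Observation,
    SiteRecord,
    design_matrix,
    exponential_covariance,
    pairwise_distances,
    SPATIAL_JITTER,
)

__all__ = [
    "DesignConfig",
    "GridConfig",
    "GridPoint",
    "default_road",
    "distance_and_side",
    "generate_design",
    "simulate_concentrations",
    "generate_prediction_grid",
    "default_truth",
    "STRATUM_BANDS",
]

#: Distance bands (m) defining the five reporting strata.
STRATUM_BANDS = ((0.0, 100.0), (100.0, 2000.0), (2000.0, 4000.0),
                 (4000.0, 5000.0), (30000.0, 64000.0))

#: Posterior-mean regression coefficients from the published monitoring
#: summaries, used as default simulation truth so synthetic datasets resemble
#: the study: (intercept, log-distance, south, interaction) per element/year.
PUBLISHED_BETA = {
    ("Cd", 2006): (3.778, -0.504, -0.471, 0.014),
    ("Cd", 2017): (4.626, -0.618, -0.466, -0.037),
    ("Pb", 2006): (7.849, -0.629, -0.498, -0.025),
    ("Pb", 2017): (6.775, -0.497, -0.239, -0.069),
    ("Zn", 2006): (9.165, -0.535, -0.766, 0.059),
    ("Zn", 2017): (9.016, -0.533, -0.626, 0.029),
}


def default_truth(element: str = "Zn", year: int = 2006) -> ModelParameters:
    """Default simulation truth: published posterior-mean coefficients plus
    plausible variance components (log-scale variances typical of duplicate
    and between-site variability; 3 km spatial range)."""
    beta = PUBLISHED_BETA[(element, year)]
    return ModelParameters(
        beta=np.array(beta),
        sigma0_sq=0.05,
        sigma1_sq=0.10,
        sigma2_sq=0.30,
        theta=3000.0,
    )


def default_road(length_m: float = 32000.0) -> LineString:
    """Default road geometry: a straight west-east segment of the given
    length along the x-axis; north is +y."""
    return LineString([(0.0, 0.0), (length_m, 0.0)])


def distance_and_side(x: float, y: float, road: LineString) -> tuple[float, str]:
    """Distance (m) from a point to the road polyline and which side it is on.

    Side is determined by the sign of the cross product of the local road
    tangent (at the nearest point) with the offset vector; the left of the
    direction of travel is "north" (for the default +x road, +y is north).
    """
    p = Point(x, y)
    s = road.project(p)
    nearest = road.interpolate(s)
    eps = min(1.0, road.length / 1000.0)
    a = road.interpolate(max(0.0, s - eps))
    b = road.interpolate(min(road.length, s + eps))
    tx, ty = b.x - a.x, b.y - a.y
    cross = tx * (y - nearest.y) - ty * (x - nearest.x)
    return float(road.distance(p)), ("north" if cross >= 0 else "south")


def _offset_point(road: LineString, along_m: float, distance_m: float, side: str
                  ) -> tuple[float, float]:
    """Point offset perpendicular from the road at arc position ``along_m``."""
    eps = min(1.0, road.length / 1000.0)
    a = road.interpolate(max(0.0, along_m - eps))
    b = road.interpolate(min(road.length, along_m + eps))
    t = np.array([b.x - a.x, b.y - a.y])
    t /= np.linalg.norm(t)
    normal = np.array([-t[1], t[0]])  # left of travel = north
    if side == "south":
        normal = -normal
    base = road.interpolate(along_m)
    return float(base.x + distance_m * normal[0]), float(base.y + distance_m * normal[1])


@dataclass
class DesignConfig:
    """Study-design parameters; defaults reproduce the monitored network."""

    n_transects: int = 12
    transect_distances: tuple[float, ...] = (10.0, 50.0, 100.0, 300.0, 1000.0, 2000.0, 4000.0)
    #: Standard plots per distance class; two transects each lack one far plot.
    plots_per_distance: dict = field(default_factory=lambda: {
        10.0: 12, 50.0: 12, 100.0: 12, 300.0: 12, 1000.0: 12, 2000.0: 11, 4000.0: 11})
    roadside_distance: float = 3.0
    n_roadside: int = 6
    autocorrelation_offset_range: tuple[float, float] = (10.0, 20.0)
    #: How many autocorrelation plots attach to a 1,000 / 2,000 / 4,000 m parent.
    autocorrelation_parent_counts: dict = field(
        default_factory=lambda: {1000.0: 8, 2000.0: 1, 4000.0: 3})
    reference_distance_ranges: tuple[tuple[float, float], ...] = (
        (42000.0, 48000.0), (60000.0, 64200.0))
    reference_counts: tuple[int, ...] = (4, 6)
    #: Field duplicates per distance class (plan totals 131 tissue samples).
    duplicate_counts: dict = field(default_factory=lambda: {
        50.0: 3, 100.0: 5, 300.0: 2, 1000.0: 2, 2000.0: 3, 4000.0: 4,
        "reference_1": 1, "reference_2": 1})
    road_geometry: LineString = field(default_factory=default_road)
    n_transects_north: int = 6
    dropout_probability: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.autocorrelation_offset_range
        if not (0 < lo <= hi):
            raise ValueError("autocorrelation offset range must be within (0, inf)")
        if any(d <= 0 for d in self.transect_distances) or self.roadside_distance <= 0:
            raise ValueError("all design distances must be positive")
        if not (0.0 <= self.dropout_probability <= 1.0):
            raise ValueError("dropout_probability must be in [0, 1]")
        if self.road_geometry is None or self.road_geometry.length == 0:
            raise ValueError("road geometry must be a non-empty polyline")


def generate_design(
    config: DesignConfig | None = None, seed: int = 0
) -> tuple[list[SiteRecord], dict[str, int]]:
    """Lay out the sampling network and plan tissue-sample counts per site.

    Returns the list of :class:`SiteRecord` and a plan mapping ``site_id`` to
    the number of tissue samples (1 plus any field duplicate; 0 if dropped
    out).  With the default configuration and ``dropout_probability=0`` the
    plan totals exactly 131 samples.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    road = config.road_geometry
    L = road.length
    sites: list[SiteRecord] = []
    plan: dict[str, int] = {}

    def add_site(site_id: str, x: float, y: float) -> SiteRecord:
        d, side = distance_and_side(x, y, road)
        rec = SiteRecord(site_id, x, y, d, side)
        sites.append(rec)
        plan[site_id] = 1
        return rec

    # Transect stations spread along the road, alternating sides by lot.
    stations = (np.arange(config.n_transects) + 0.5) / config.n_transects * L
    side_lot = np.array(["north"] * config.n_transects_north +
                        ["south"] * (config.n_transects - config.n_transects_north))
    rng.shuffle(side_lot)

    # Which transects lack a plot at a given distance (Table-1-style 11/12).
    missing: dict[float, set[int]] = {}
    for d in config.transect_distances:
        n_plots = config.plots_per_distance.get(d, config.n_transects)
        n_missing = config.n_transects - n_plots
        missing[d] = set(rng.choice(config.n_transects, size=n_missing, replace=False)) \
            if n_missing > 0 else set()

    # Autocorrelation parents: one per transect, drawn from the configured
    # multiset, avoiding transects whose parent plot is missing.
    parent_pool = [d for d, c in config.autocorrelation_parent_counts.items()
                   for _ in range(c)]
    if len(parent_pool) != config.n_transects:
        raise ValueError("autocorrelation parent counts must sum to n_transects")
    for _ in range(1000):
        rng.shuffle(parent_pool)
        if all(t not in missing.get(parent_pool[t], set())
               for t in range(config.n_transects)):
            break
    else:  # pragma: no cover - unreachable with valid configs
        raise ValueError("could not assign autocorrelation parents to transects")

    plot_sites: dict[tuple[int, float], SiteRecord] = {}
    for t in range(config.n_transects):
        side = side_lot[t]
        for d in config.transect_distances:
            if t in missing[d]:
                continue
            along = float(np.clip(stations[t] + rng.uniform(-200.0, 200.0), 0.0, L))
            x, y = _offset_point(road, along, d, side)
            rec = add_site(f"T{t + 1:02d}-{int(d)}m", x, y)
            plot_sites[(t, d)] = rec

    # Autocorrelation plots offset 10-20 m from their parent plot.
    lo, hi = config.autocorrelation_offset_range
    for t in range(config.n_transects):
        parent = plot_sites[(t, parent_pool[t])]
        offset = rng.uniform(lo, hi)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        x = parent.easting + offset * np.cos(angle)
        y = parent.northing + offset * np.sin(angle)
        add_site(f"T{t + 1:02d}-AC", x, y)

    # Roadside tissue-only points at 3 m, split across sides.
    for r in range(config.n_roadside):
        along = rng.uniform(0.0, L)
        side = "north" if r < config.n_roadside // 2 else "south"
        x, y = _offset_point(road, along, config.roadside_distance, side)
        add_site(f"RS{r + 1}", x, y)

    # Reference sites far south of the road.
    for g, ((dlo, dhi), count) in enumerate(
            zip(config.reference_distance_ranges, config.reference_counts), start=1):
        for r in range(count):
            along = rng.uniform(0.1 * L, 0.9 * L)
            d = rng.uniform(dlo, dhi)
            x, y = _offset_point(road, along, d, "south")
            add_site(f"REF{g}-{r + 1}", x, y)

    # Field duplicates: per distance class, assigned to plots drawn by lot.
    def class_members(key) -> list[str]:
        if key == "reference_1":
            return [s.site_id for s in sites if s.site_id.startswith("REF1")]
        if key == "reference_2":
            return [s.site_id for s in sites if s.site_id.startswith("REF2")]
        return [rec.site_id for (t, d), rec in plot_sites.items() if d == key]

    for key, n_dup in config.duplicate_counts.items():
        members = class_members(key)
        for sid in rng.choice(members, size=n_dup, replace=False):
            plan[str(sid)] += 1

    if config.dropout_probability > 0:
        for s in sites:
            if rng.uniform() < config.dropout_probability:
                plan[s.site_id] = 0

    return sites, plan


def simulate_concentrations(
    sites: list[SiteRecord],
    plan: dict[str, int],
    params: ModelParameters,
    element: str = "Zn",
    year: int = 2006,
    seed: int = 0,
) -> list[Observation]:
    """Draw one dataset from the generative model.

    eta is drawn jointly from N(0, Sigma) over the sites, alpha i.i.d.
    N(0, sigma1_sq), and each planned tissue sample gets its own measurement
    error; concentrations are ``exp`` of the log-scale sum, hence positive.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    X = design_matrix(sites)
    Sigma = exponential_covariance(pairwise_distances(sites), params.sigma2_sq, params.theta)
    L = np.linalg.cholesky(Sigma + SPATIAL_JITTER * params.sigma2_sq * np.eye(n))
    eta = L @ rng.standard_normal(n)
    alpha = rng.normal(0.0, np.sqrt(params.sigma1_sq), size=n)
    mu = X @ params.beta + alpha + eta

    observations: list[Observation] = []
    for i, s in enumerate(sites):
        for j in range(plan.get(s.site_id, 0)):
            eps = rng.normal(0.0, np.sqrt(params.sigma0_sq))
            observations.append(Observation(
                site_id=s.site_id, element=element, year=year,
                replicate_index=j + 1, concentration=float(np.exp(mu[i] + eps))))
    return observations


@dataclass(frozen=True)
class GridPoint:
    """One prediction-grid location with its distance stratum."""

    grid_id: str
    easting: float
    northing: float
    distance_to_road: float
    side: str
    stratum: int

    def __post_init__(self) -> None:
        lo, hi = STRATUM_BANDS[self.stratum - 1]
        d = self.distance_to_road
        ok = (lo <= d <= hi) if self.stratum == 5 else (lo < d <= hi)
        if not ok:
            raise ValueError(
                f"grid point {self.grid_id!r}: distance {d} m inconsistent "
                f"with stratum {self.stratum} band ({lo}, {hi}]")
        if self.stratum == 5 and self.side != "south":
            raise ValueError("stratum 5 occurs only on the south side of the road")


@dataclass
class GridConfig:
    """Prediction-grid densities per stratum and side; defaults match the
    published per-stratum counts (totals 697, 743, 507, 121, 289)."""

    counts_north: tuple[int, ...] = (351, 360, 215, 46, 0)
    counts_south: tuple[int, ...] = (346, 383, 292, 75, 289)
    stratum_bands: tuple[tuple[float, float], ...] = STRATUM_BANDS
    road_geometry: LineString = field(default_factory=default_road)

    def __post_init__(self) -> None:
        if len(self.counts_north) != len(self.stratum_bands) or \
           len(self.counts_south) != len(self.stratum_bands):
            raise ValueError("need one count per stratum and side")
        for lo, hi in self.stratum_bands:
            if hi <= lo:
                raise ValueError(f"stratum band ({lo}, {hi}) has zero width")
        if len(self.stratum_bands) >= 5 and self.counts_north[4] != 0:
            raise ValueError("stratum 5 occurs only on the south side")


def generate_prediction_grid(config: GridConfig | None = None, seed: int = 0
                             ) -> list[GridPoint]:
    """Scatter grid points along the road with distances drawn uniformly
    within each stratum band, at the configured per-stratum/side densities."""
    config = config or GridConfig()
    rng = np.random.default_rng(seed)
    road = config.road_geometry
    L = road.length
    grid: list[GridPoint] = []
    k = 0
    for stratum, (lo, hi) in enumerate(config.stratum_bands, start=1):
        for side, count in (("north", config.counts_north[stratum - 1]),
                            ("south", config.counts_south[stratum - 1])):
            for _ in range(count):
                along = rng.uniform(0.0, L)
                # open at the lower edge so strata partition the distances
                d = rng.uniform(np.nextafter(lo, hi) if stratum != 5 else lo, hi)
                x, y = _offset_point(road, along, d, side)
                k += 1
                grid.append(GridPoint(f"G{k:05d}", x, y, d, side, stratum))
    return grid
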