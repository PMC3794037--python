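"""Synthetic landscape generation.

The survey design this package evaluates rests on three spatial facts
about the study system: host trees are clustered and over-represented
along roads (stand-edge effect), nest occurrence follows a colonisation
front, and nests are spatially aggregated beyond what the tree pattern
alone induces.  Each generator below reproduces one of these features
with the simplest process that exhibits it.

* Roads: town centres drawn uniformly, straight connector polylines
  between neighbouring towns, plus short random streets whose placement
  is biased toward towns.  The expected total length matches
  ``density * area`` exactly (the street count is Poisson with the
  residual length budget as mean).
* Host trees: a Thomas-type cluster process — Poisson parents, Gaussian
  offspring — with the parent intensity multiplied inside a band around
  roads.
* Occupancy: a logistic front along one axis.
* Nests: Bernoulli thinning of trees by the occupancy probability,
  driven through a Gaussian copula on a smoothed stationary random
  field, so nests aggregate while the marginal occupancy probability is
  preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm
from shapely import STRtree
from shapely.geometry import Point

from .rng import substream
from .types import Extent, HostTree, NestSite, RoadNetwork, RoadSegment, as_segment_list

__all__ = [
    "OccupancySurface",
    "generate_roads",
    "generate_host_trees",
    "make_front_occupancy",
    "place_nests",
]

# local street stick length, km; short relative to both grains of interest
_STREET_LENGTH = 1.0
# fraction of local streets attached to a town nucleus (when towns exist)
_TOWN_WEIGHT = 0.6


@dataclass(frozen=True)
class OccupancySurface:
    """Probability that a host tree at (x, y) carries at least one nest.

    Wraps a vectorised function extent -> [0, 1].
    """

    extent: Extent
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __call__(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = np.asarray(self.func(x, y), dtype=float)
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("occupancy surface returned values outside [0, 1]")
        return p


def _nearest_distances(points: np.ndarray, geoms: list) -> np.ndarray:
    """Distance from each point (n x 2) to its nearest geometry."""
    if len(geoms) == 0:
        return np.full(len(points), np.inf)
    tree = STRtree(geoms)
    pts = [Point(p) for p in points]
    idx = tree.nearest(pts)
    return np.array([pts[i].distance(geoms[j]) for i, j in enumerate(np.atleast_1d(idx))])


def generate_roads(
    extent: Extent,
    density: float,
    n_towns: int,
    seed: int,
    street_length: float = _STREET_LENGTH,
) -> RoadNetwork:
    """Generate a synthetic planar road network.

    Parameters
    ----------
    extent : study area, km.
    density : target road length per unit area, km / km^2.  The expected
        total length is ``density * extent.area``.
    n_towns : number of town centres (uniform in the extent).  Streets
        concentrate around towns, which is what makes street-imagery
        coverage spatially biased later on.
    seed : integer master seed (stage substream ``"roads"``).
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if n_towns < 0:
        raise ValueError("n_towns must be >= 0")
    rng = substream(seed, "roads")
    towns = [
        (float(x), float(y))
        for x, y in zip(
            rng.uniform(extent.x_min, extent.x_max, n_towns),
            rng.uniform(extent.y_min, extent.y_max, n_towns),
        )
    ]
    if density == 0:
        return RoadNetwork(segments=[], towns=towns, seed=seed)

    target = density * extent.area
    segments: list[RoadSegment] = []
    used = 0.0

    # backbone: each town connects to its nearest predecessor, while the
    # length budget allows
    for i in range(1, len(towns)):
        prev = np.asarray(towns[:i])
        here = np.asarray(towns[i])
        d = np.hypot(*(prev - here).T)
        j = int(np.argmin(d))
        if used + d[j] > target:
            continue
        segments.append(
            RoadSegment(id=f"c{i:04d}", vertices=[towns[j], towns[i]])
        )
        used += d[j]

    # local streets: Poisson count with the residual budget as mean length
    residual = max(target - used, 0.0)
    n_local = rng.poisson(residual / street_length)
    town_sd = 0.15 * min(extent.width, extent.height)
    half = street_length / 2.0
    k = 0
    attempts = 0
    while k < n_local and attempts < 200 * n_local + 1000:
        attempts += 1
        if towns and rng.random() < _TOWN_WEIGHT:
            tx, ty = towns[rng.integers(len(towns))]
            cx = rng.normal(tx, town_sd)
            cy = rng.normal(ty, town_sd)
        else:
            cx = rng.uniform(extent.x_min, extent.x_max)
            cy = rng.uniform(extent.y_min, extent.y_max)
        theta = rng.uniform(0, math.pi)
        dx, dy = half * math.cos(theta), half * math.sin(theta)
        p0 = (cx - dx, cy - dy)
        p1 = (cx + dx, cy + dy)
        if not (extent.contains(*p0) and extent.contains(*p1)):
            continue
        segments.append(RoadSegment(id=f"s{k:05d}", vertices=[p0, p1]))
        k += 1
    return RoadNetwork(segments=segments, towns=towns, seed=seed)


def generate_host_trees(
    roads: RoadNetwork | Sequence[RoadSegment],
    extent: Extent,
    base_intensity: float,
    roadside_multiplier: float,
    roadside_band: float,
    cluster_sd: float,
    mean_cluster_size: float,
    seed: int,
) -> list[HostTree]:
    """Thomas-type clustered host trees with a roadside boost.

    Poisson parents with intensity ``base_intensity / mean_cluster_size``
    away from roads, multiplied by ``roadside_multiplier`` within
    ``roadside_band`` of the nearest road (simulated by thinning at the
    band maximum); each parent spawns Poisson(``mean_cluster_size``)
    offspring displaced by an isotropic Gaussian of sd ``cluster_sd``.
    Offspring falling outside the extent are dropped.
    """
    if base_intensity < 0:
        raise ValueError("base_intensity must be >= 0")
    if roadside_multiplier < 1:
        raise ValueError("roadside_multiplier must be >= 1")
    if roadside_band < 0:
        raise ValueError("roadside_band must be >= 0")
    if cluster_sd < 0:
        raise ValueError("cluster_sd must be >= 0")
    if mean_cluster_size < 1:
        raise ValueError("mean_cluster_size must be >= 1")
    segs = as_segment_list(roads)
    if base_intensity == 0:
        return []
    rng = substream(seed, "trees")
    geoms = [s.geometry for s in segs]
    kappa = base_intensity / mean_cluster_size
    lam_max = kappa * roadside_multiplier
    n_cand = rng.poisson(lam_max * extent.area)
    cand = np.column_stack(
        [
            rng.uniform(extent.x_min, extent.x_max, n_cand),
            rng.uniform(extent.y_min, extent.y_max, n_cand),
        ]
    )
    if n_cand:
        d = _nearest_distances(cand, geoms)
        accept_p = np.where(d <= roadside_band, 1.0, 1.0 / roadside_multiplier)
        parents = cand[rng.random(n_cand) < accept_p]
    else:
        parents = cand

    offspring = []
    for px, py in parents:
        m = rng.poisson(mean_cluster_size)
        if m == 0:
            continue
        xs = rng.normal(px, cluster_sd, m)
        ys = rng.normal(py, cluster_sd, m)
        offspring.append(np.column_stack([xs, ys]))
    if not offspring:
        return []
    pts = np.vstack(offspring)
    inside = (
        (pts[:, 0] >= extent.x_min)
        & (pts[:, 0] < extent.x_max)
        & (pts[:, 1] >= extent.y_min)
        & (pts[:, 1] < extent.y_max)
    )
    pts = pts[inside]
    dist = _nearest_distances(pts, geoms)
    return [
        HostTree(location=(float(x), float(y)), dist_to_road=float(dr))
        for (x, y), dr in zip(pts, dist)
    ]


def make_front_occupancy(
    extent: Extent,
    front_position: float,
    front_width: float,
    p_behind: float,
    p_ahead: float,
    axis: str = "x",
) -> OccupancySurface:
    """Logistic colonisation front along one axis.

    Occupancy decays from ``p_behind`` (colonised side, low coordinate)
    to ``p_ahead`` (front of the expansion, high coordinate), crossing
    the midpoint value at ``front_position``.  ``front_width`` sets the
    width of the transition; zero gives a hard step.
    """
    if not (0.0 <= p_ahead <= p_behind <= 1.0):
        raise ValueError("require 0 <= p_ahead <= p_behind <= 1")
    if front_width < 0:
        raise ValueError("front_width must be >= 0")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")

    def func(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        t = x if axis == "x" else y
        t = np.asarray(t, dtype=float)
        if front_width == 0:
            p = np.where(t < front_position, p_behind, p_ahead)
            return np.where(t == front_position, (p_behind + p_ahead) / 2.0, p)
        z = np.clip((t - front_position) / (front_width / 4.0), -500, 500)
        return p_ahead + (p_behind - p_ahead) / (1.0 + np.exp(z))

    return OccupancySurface(extent=extent, func=func)


def _correlated_uniforms(
    pts: np.ndarray, extent: Extent, aggregation_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Marginally Uniform(0,1) draws with spatial correlation.

    White noise on a lattice is smoothed with a Gaussian kernel
    (sd = aggregation_range / 2 in km), standardised by the exact kernel
    variance, and read at the nearest lattice node, so every value is an
    exact standard normal; the probability integral transform then gives
    exact uniforms.  The lattice is padded by the kernel support so no
    edge effect perturbs the marginal.
    """
    sigma_km = aggregation_range / 2.0
    res = max(sigma_km / 1.5, max(extent.width, extent.height) / 512.0)
    sigma_px = sigma_km / res
    pad = int(math.ceil(4 * sigma_px)) + 1
    nx = int(math.ceil(extent.width / res)) + 1
    ny = int(math.ceil(extent.height / res)) + 1
    noise = rng.standard_normal((ny + 2 * pad, nx + 2 * pad))
    smooth = gaussian_filter(noise, sigma=sigma_px, mode="constant", truncate=4.0)
    # exact variance of the separable truncated kernel
    imp = np.zeros(2 * pad + 1)
    imp[pad] = 1.0
    w = gaussian_filter(imp, sigma=sigma_px, mode="constant", truncate=4.0)
    var1d = float(np.sum(w**2))
    z = smooth[pad : pad + ny, pad : pad + nx] / math.sqrt(var1d * var1d)
    ix = np.clip(np.round((pts[:, 0] - extent.x_min) / res).astype(int), 0, nx - 1)
    iy = np.clip(np.round((pts[:, 1] - extent.y_min) / res).astype(int), 0, ny - 1)
    return norm.cdf(z[iy, ix])


def place_nests(
    trees: Sequence[HostTree],
    occ: OccupancySurface,
    aggregation_range: float,
    seed: int,
    mean_extra_nests: float = 1.0,
) -> list[NestSite]:
    """Thin host trees into nest sites by the occupancy surface.

    Each tree carries a nest with probability ``occ(location)`` exactly
    (marginally), but the Bernoulli draws are driven by a spatially
    correlated field with correlation range ``aggregation_range`` km, so
    occupied trees clump.  ``aggregation_range = 0`` gives independent
    thinning.  Nest counts per occupied tree are 1 + Poisson with mean
    ``mean_extra_nests``.
    """
    if aggregation_range < 0:
        raise ValueError("aggregation_range must be >= 0")
    trees = list(trees)
    if not trees:
        return []
    rng = substream(seed, "nests")
    pts = np.asarray([t.location for t in trees], dtype=float)
    p = occ(pts[:, 0], pts[:, 1])
    if aggregation_range == 0:
        u = rng.random(len(trees))
    else:
        u = _correlated_uniforms(pts, occ.extent, aggregation_range, rng)
    keep = u < p
    n_extra = rng.poisson(mean_extra_nests, size=len(trees))
    return [
        NestSite(location=t.location, n_nests=int(1 + e))
        for t, k, e in zip(trees, keep, n_extra)
        if k
    ]
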