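"""Street-imagery coverage of the road network.

Two stages: (1) decide which road segments are present in the imagery
database — a Bernoulli draw per segment whose probability rises toward
town centres, reproducing the urban bias of real street-imagery fleets;
(2) rasterize each sampling cell on a fine pixel lattice (default
0.25 km) and express coverage as the proportion of the cell's pixels
touched by a covered road.

The index denominator is all pixels of the cell, not road pixels only:
a big cell crossed by one covered lane scores low even though 100 % of
its roads are covered.  The road-pixel denominator is also available
(``road_fraction_covered``) for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import box

from .grid import Cell
from .rng import substream
from .types import RoadNetwork, RoadSegment, as_segment_list

__all__ = [
    "CoverageRaster",
    "CoverageIndex",
    "assign_coverage",
    "rasterize_cell",
    "coverage_index",
    "road_fraction_covered",
]


@dataclass
class CoverageRaster:
    """Boolean pixel grid for one cell: pixel intersects a qualifying road.

    Pixels are anchored at the cell's SW corner; a resolution that does
    not divide the cell size truncates the final row/column at the cell
    boundary.  Pixel membership is closed-square: touching the boundary
    counts.
    """

    cell_id: tuple[int, int]
    resolution: float
    pixels: np.ndarray  # bool, shape (n, n), row 0 = southmost

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())

    @property
    def n_total(self) -> int:
        return int(self.pixels.size)

    def to_ascii(self) -> str:
        """ASCII-grid-style dump, north row first."""
        lines = [
            f"ncols {self.pixels.shape[1]}",
            f"nrows {self.pixels.shape[0]}",
            f"cellsize {self.resolution}",
        ]
        for row in self.pixels[::-1]:
            lines.append(" ".join("1" if v else "0" for v in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CoverageIndex:
    cell_id: tuple[int, int]
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("coverage index must lie in [0, 1]")


def assign_coverage(
    roads: RoadNetwork | Sequence[RoadSegment],
    base_p: float,
    town_boost: float,
    town_range: float,
    seed: int,
    towns: Sequence[tuple[float, float]] | None = None,
) -> list[RoadSegment]:
    """Set the ``covered`` flag on every segment (in place; also returned).

    Per-segment coverage probability is
    ``clamp(base_p + town_boost * exp(-d / town_range), 0, 1)`` where d
    is the distance from the segment midpoint to the nearest town.  With
    no towns (or ``town_boost = 0``) coverage is homogeneous Bernoulli.
    """
    if not 0.0 <= base_p <= 1.0:
        raise ValueError("base_p must lie in [0, 1]")
    if town_boost < 0:
        raise ValueError("town_boost must be >= 0")
    if town_range <= 0:
        raise ValueError("town_range must be > 0")
    segs = as_segment_list(roads)
    if towns is None and isinstance(roads, RoadNetwork):
        towns = roads.towns
    towns = list(towns or [])
    rng = substream(seed, "coverage")
    if segs:
        draws = rng.random(len(segs))
        for s, u in zip(segs, draws):
            p = base_p
            if towns and town_boost > 0:
                mid = s.geometry.interpolate(0.5, normalized=True)
                d = min(math.hypot(mid.x - tx, mid.y - ty) for tx, ty in towns)
                p = base_p + town_boost * math.exp(-d / town_range)
            s.covered = bool(u < min(max(p, 0.0), 1.0))
    return segs


def _pixel_edges(cell: Cell, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(math.ceil(cell.mesh / resolution))
    xs = cell.x0 + resolution * np.arange(n + 1)
    ys = cell.y0 + resolution * np.arange(n + 1)
    # truncate the final row/column at the cell boundary
    xs[-1] = min(xs[-1], cell.x0 + cell.mesh)
    ys[-1] = min(ys[-1], cell.y0 + cell.mesh)
    return xs, ys


def rasterize_cell(
    cell: Cell,
    roads: RoadNetwork | Sequence[RoadSegment],
    resolution: float = 0.25,
    covered_only: bool = True,
) -> CoverageRaster:
    """Rasterize a cell: pixel true iff >= 1 qualifying road intersects it.

    ``covered_only`` restricts the qualifying roads to those in the
    imagery database.  Intersection is against the closed pixel square,
    so a road running along a pixel edge marks that pixel.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    segs = as_segment_list(roads)
    if covered_only:
        segs = [s for s in segs if s.covered]
    xs, ys = _pixel_edges(cell, resolution)
    n = len(xs) - 1
    pix = np.zeros((n, n), dtype=bool)
    geoms = [s.geometry for s in segs]
    if geoms:
        tree = STRtree(geoms)
        cell_geom = cell.geometry
        hits = tree.query(cell_geom, predicate="intersects")
        local = [geoms[i] for i in np.atleast_1d(hits)]
        if local:
            ltree = STRtree(local)
            for r in range(n):
                for c in range(n):
                    sq = box(xs[c], ys[r], xs[c + 1], ys[r + 1])
                    if len(ltree.query(sq, predicate="intersects")):
                        pix[r, c] = True
    return CoverageRaster(cell_id=cell.id, resolution=resolution, pixels=pix)


def coverage_index(
    cell: Cell,
    roads: RoadNetwork | Sequence[RoadSegment],
    resolution: float = 0.25,
) -> CoverageIndex:
    """Proportion of the cell's pixels intersecting an imagery-covered road."""
    ras = rasterize_cell(cell, roads, resolution=resolution, covered_only=True)
    return CoverageIndex(cell_id=cell.id, value=ras.n_true / ras.n_total)


def road_fraction_covered(
    cell: Cell,
    roads: RoadNetwork | Sequence[RoadSegment],
    resolution: float = 0.25,
) -> float:
    """Covered-road pixels over all road pixels (alternative denominator).

    Returns nan when the cell holds no road pixel at all.
    """
    cov = rasterize_cell(cell, roads, resolution=resolution, covered_only=True)
    allr = rasterize_cell(cell, roads, resolution=resolution, covered_only=False)
    if allr.n_true == 0:
        return float("nan")
    return cov.n_true / allr.n_true
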