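"""Core domain types: extents, road segments, host trees, nest sites.

All coordinates are planar kilometres with the origin at the lower-left
corner of the study extent.  No geographic projection is used; the
analysis is scale- and location-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from shapely.geometry import LineString, Point

WINTER = "WINTER"
OTHER = "OTHER"

__all__ = ["Extent", "RoadSegment", "RoadNetwork", "HostTree", "NestSite", "WINTER", "OTHER"]


@dataclass(frozen=True)
class Extent:
    """Axis-aligned rectangular study area, km."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError(f"extent requires x_max > x_min, got x_min={self.x_min}, x_max={self.x_max}")
        if not self.y_max > self.y_min:
            raise ValueError(f"extent requires y_max > y_min, got y_min={self.y_min}, y_max={self.y_max}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership: [x_min, x_max) x [y_min, y_max)."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass
class RoadSegment:
    """A road polyline; the observation substrate of every survey.

    ``covered`` marks membership in the street-imagery database;
    ``image_season`` records the season of panoramic capture (winter
    nests are only conspicuous on winter imagery).
    """

    id: str
    vertices: list[tuple[float, float]]
    covered: bool = False
    image_season: str = WINTER
    _geom: LineString | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError(f"road segment {self.id!r} needs >= 2 vertices")
        if self.image_season not in (WINTER, OTHER):
            raise ValueError(f"image_season must be {WINTER!r} or {OTHER!r}")
        if not math.isfinite(self.length) or self.length <= 0:
            raise ValueError(f"road segment {self.id!r} must have finite positive length")

    @property
    def geometry(self) -> LineString:
        if self._geom is None:
            self._geom = LineString(self.vertices)
        return self._geom

    @property
    def length(self) -> float:
        return LineString(self.vertices).length


@dataclass
class RoadNetwork:
    """A set of road segments plus the town centres that shaped them.

    Town locations are kept because street-imagery coverage is biased
    toward towns; the coverage model needs them.
    """

    segments: list[RoadSegment]
    towns: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    def covered_segments(self) -> list[RoadSegment]:
        return [s for s in self.segments if s.covered]


@dataclass
class HostTree:
    """A potential host tree with its distance to the nearest road."""

    location: tuple[float, float]
    dist_to_road: float

    def __post_init__(self) -> None:
        if self.dist_to_road < 0:
            raise ValueError("dist_to_road must be >= 0")

    @property
    def point(self) -> Point:
        return Point(self.location)


@dataclass
class NestSite:
    """A host tree carrying at least one winter nest (ground truth)."""

    location: tuple[float, float]
    n_nests: int = 1

    def __post_init__(self) -> None:
        if self.n_nests < 1:
            raise ValueError("n_nests must be >= 1")

    @property
    def point(self) -> Point:
        return Point(self.location)


def as_segment_list(roads: RoadNetwork | Sequence[RoadSegment]) -> list[RoadSegment]:
    """Accept either a RoadNetwork or a bare sequence of segments."""
    if isinstance(roads, RoadNetwork):
        return roads.segments
    return list(roads)
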