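"""Plain-text interchange: GeoJSON for geometry, CSV for tables.

Every geometry file carries the generating seed in the top-level
``metadata`` member so a landscape can be regenerated from its file
alone.  Coordinates are planar km (no CRS member is written).
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .coverage import CoverageIndex, CoverageRaster
from .grid import SamplingGrid
from .survey import CellStatus
from .types import HostTree, NestSite, RoadNetwork, RoadSegment

__all__ = [
    "roads_to_geojson",
    "roads_from_geojson",
    "points_to_geojson",
    "nests_from_geojson",
    "grid_to_geojson",
    "grid_to_csv",
    "statuses_to_csv",
    "statuses_from_csv",
    "raster_to_csv",
    "indices_to_csv",
]


def _feature_collection(features: list[dict], seed: int | None) -> dict:
    fc: dict = {"type": "FeatureCollection", "features": features}
    if seed is not None:
        fc["metadata"] = {"seed": seed}
    return fc


def roads_to_geojson(network: RoadNetwork, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [list(v) for v in s.vertices],
            },
            "properties": {
                "id": s.id,
                "covered": s.covered,
                "image_season": s.image_season,
            },
        }
        for s in network.segments
    ]
    with open(path, "w") as fh:
        json.dump(_feature_collection(features, network.seed), fh)


def roads_from_geojson(path) -> RoadNetwork:
    with open(path) as fh:
        fc = json.load(fh)
    segments = [
        RoadSegment(
            id=f["properties"]["id"],
            vertices=[tuple(c) for c in f["geometry"]["coordinates"]],
            covered=bool(f["properties"].get("covered", False)),
            image_season=f["properties"].get("image_season", "WINTER"),
        )
        for f in fc["features"]
    ]
    return RoadNetwork(segments=segments, seed=fc.get("metadata", {}).get("seed"))


def points_to_geojson(
    points: Sequence[HostTree | NestSite], path, seed: int | None = None
) -> None:
    """Host trees or nest sites as GeoJSON Point features."""
    features = []
    for p in points:
        props: dict = {}
        if isinstance(p, NestSite):
            props["n_nests"] = p.n_nests
        else:
            props["dist_to_road"] = p.dist_to_road
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(p.location)},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump(_feature_collection(features, seed), fh)


def nests_from_geojson(path) -> list[NestSite]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        NestSite(
            location=tuple(f["geometry"]["coordinates"]),
            n_nests=int(f["properties"].get("n_nests", 1)),
        )
        for f in fc["features"]
    ]


def grid_to_geojson(grid: SamplingGrid, path) -> None:
    features = []
    for c in grid.cells:
        x0, y0, x1, y1 = c.bounds
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
                },
                "properties": {"row": c.row, "col": c.col, "mesh": c.mesh},
            }
        )
    with open(path, "w") as fh:
        json.dump(_feature_collection(features, None), fh)


def grid_to_csv(grid: SamplingGrid, path) -> None:
    pd.DataFrame(
        {
            "cell_id": [f"{c.row}_{c.col}" for c in grid.cells],
            "x0": [c.x0 for c in grid.cells],
            "y0": [c.y0 for c in grid.cells],
            "mesh": [c.mesh for c in grid.cells],
        }
    ).to_csv(path, index=False)


def _cid_str(cid) -> str:
    if isinstance(cid, tuple):
        return f"{cid[0]}_{cid[1]}"
    return str(cid)


def statuses_to_csv(statuses: Sequence[CellStatus], protocol: str, path) -> None:
    pd.DataFrame(
        {
            "cell_id": [_cid_str(s.cell_id) for s in statuses],
            "protocol": protocol,
            "status": [s.status.value for s in statuses],
            "n_detected": [s.n_detected for s in statuses],
        }
    ).to_csv(path, index=False)


def statuses_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def raster_to_csv(raster: CoverageRaster, path) -> None:
    rows, cols = raster.pixels.shape
    pd.DataFrame(
        {
            "cell_id": _cid_str(raster.cell_id),
            "pixel_row": [r for r in range(rows) for _ in range(cols)],
            "pixel_col": [c for _ in range(rows) for c in range(cols)],
            "flag": raster.pixels.astype(int).ravel(),
        }
    ).to_csv(path, index=False)


def indices_to_csv(indices: Sequence[CoverageIndex], path) -> None:
    pd.DataFrame(
        {
            "cell_id": [_cid_str(i.cell_id) for i in indices],
            "index": [i.value for i in indices],
        }
    ).to_csv(path, index=False)
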