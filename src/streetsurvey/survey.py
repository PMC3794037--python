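"""Field and street-imagery survey protocols.

Both protocols scan a landscape cell by cell from the road network and
return one four-valued status per cell.

Field protocol: crews drive every road (covered by imagery or not) and
check host trees by eye and binoculars; a cell is PRESENCE as soon as
one nest is sighted, ABSENCE once all roads have been driven without a
detection.  The field survey never returns NO_DATA.

Imagery protocol: a virtual operator only sees roads present in the
imagery database (optionally only those photographed in winter, when
nests are conspicuous).  A cell with no observable road at all is
NO_DATA; an unambiguous detection (within ``clear_radius``) makes it
PRESENCE; detections only in the marginal band
(``clear_radius``, ``detect_radius``] leave a persistent doubt —
INDISTINCT; otherwise ABSENCE.

Detection is a distance-thresholded Bernoulli per nest: a nest within
``detect_radius`` of an observable road is detected with probability
``p_detect``, independently across nests.  Detections are credited to
the cell containing the nest; the sighting road may lie just across a
cell boundary, as in real georeferenced roadside records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from shapely import STRtree

from .grid import SamplingGrid, locate
from .landscape import _nearest_distances
from .rng import substream
from .types import WINTER, NestSite, RoadNetwork, RoadSegment, as_segment_list

__all__ = ["Status", "CellStatus", "DetectionConfig", "field_survey", "imagery_survey"]


class Status(str, Enum):
    PRESENCE = "PRESENCE"
    ABSENCE = "ABSENCE"
    INDISTINCT = "INDISTINCT"
    NO_DATA = "NO_DATA"


@dataclass
class CellStatus:
    cell_id: tuple[int, int]
    status: Status
    n_detected: int = 0
    detected_nest_ids: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class DetectionConfig:
    """Distances (km) and per-nest detection probability of a protocol.

    ``clear_radius`` bounds unambiguous identification; between it and
    ``detect_radius`` a nest is sighted but doubtful (imagery only).
    """

    detect_radius: float = 0.3
    clear_radius: float = 0.05
    p_detect: float = 1.0
    respect_season: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.clear_radius <= self.detect_radius:
            raise ValueError("require 0 < clear_radius <= detect_radius")
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError("p_detect must lie in [0, 1]")


FIELD_CONFIG = DetectionConfig(detect_radius=0.3, clear_radius=0.3, p_detect=1.0)
IMAGERY_CONFIG = DetectionConfig(
    detect_radius=0.1, clear_radius=0.05, p_detect=0.95, respect_season=False
)


def _survey(
    grid: SamplingGrid,
    nests: Sequence[NestSite],
    observable: list[RoadSegment],
    cfg: DetectionConfig,
    rng: np.random.Generator,
    imagery: bool,
) -> list[CellStatus]:
    nests = list(nests)
    geoms = [s.geometry for s in observable]
    if nests:
        pts = np.asarray([n.location for n in nests], dtype=float)
        d = _nearest_distances(pts, geoms)
        draws = rng.random(len(nests))
        detected = (d <= cfg.detect_radius) & (draws < cfg.p_detect)
        clear = detected & (d <= cfg.clear_radius)
    else:
        detected = clear = np.zeros(0, dtype=bool)

    per_cell: dict[tuple[int, int], dict] = {
        c.id: {"clear": [], "marginal": []} for c in grid.cells
    }
    for i, nest in enumerate(nests):
        cid = locate(nest.location, grid)
        if cid is None or not detected[i]:
            continue
        per_cell[cid]["clear" if clear[i] else "marginal"].append(i)

    no_data: set[tuple[int, int]] = set()
    if imagery:
        tree = STRtree(geoms) if geoms else None
        for c in grid.cells:
            if tree is None or len(tree.query(c.geometry, predicate="intersects")) == 0:
                no_data.add(c.id)

    out = []
    for c in grid.cells:
        hits = per_cell[c.id]
        ids = hits["clear"] + hits["marginal"]
        if imagery and c.id in no_data:
            status = Status.NO_DATA
            ids = []
        elif hits["clear"]:
            status = Status.PRESENCE
        elif hits["marginal"]:
            status = Status.INDISTINCT if imagery else Status.PRESENCE
        else:
            status = Status.ABSENCE
        out.append(
            CellStatus(
                cell_id=c.id,
                status=status,
                n_detected=len(ids),
                detected_nest_ids=ids,
            )
        )
    return out


def field_survey(
    grid: SamplingGrid,
    nests: Sequence[NestSite],
    roads: RoadNetwork | Sequence[RoadSegment],
    cfg: DetectionConfig = FIELD_CONFIG,
    seed: int = 0,
) -> list[CellStatus]:
    """Exhaustive drive-by survey; statuses are PRESENCE or ABSENCE only.

    All roads are usable regardless of imagery coverage.  Any detection
    within ``cfg.detect_radius`` (Bernoulli ``p_detect``) makes the
    nest's cell PRESENCE; the clear/marginal distinction does not apply
    in the field (binoculars resolve doubt).
    """
    rng = substream(seed, "field_survey")
    return _survey(grid, nests, as_segment_list(roads), cfg, rng, imagery=False)


def imagery_survey(
    grid: SamplingGrid,
    nests: Sequence[NestSite],
    roads: RoadNetwork | Sequence[RoadSegment],
    cfg: DetectionConfig = IMAGERY_CONFIG,
    seed: int = 0,
) -> list[CellStatus]:
    """Virtual drive of imagery-covered roads; four-valued statuses.

    Only segments flagged ``covered`` are observable, and only those
    with winter imagery if ``cfg.respect_season``.  NO_DATA marks cells
    with no observable road at all.
    """
    segs = [s for s in as_segment_list(roads) if s.covered]
    if cfg.respect_season:
        segs = [s for s in segs if s.image_season == WINTER]
    rng = substream(seed, "imagery_survey")
    return _survey(grid, nests, segs, cfg, rng, imagery=True)
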