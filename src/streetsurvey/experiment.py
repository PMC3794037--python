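"""End-to-end scale experiments.

A scenario fixes one synthetic landscape recipe (roads, coverage,
trees, occupancy front, nests) and the two survey protocols; an
experiment replays it over replicates and reads each replicate's
landscape at several grains.  The same landscape realisation is reused
across grains within a replicate — a paired design that isolates the
grain effect from landscape-to-landscape noise, mirroring a small grid
nested inside a large one.

The default ``beauce_like`` scenario emulates an intensively farmed
plain with scattered pine plantations: a 22 x 22 km window, a rural
road density of 1.5 km/km^2 concentrated around three towns, sparse
clustered host trees boosted along roads, a colonisation front
entering from the west, and street-imagery coverage of roughly half
the segments, higher near towns.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import AgreementMetrics, ConfusionMatrix, confusion, metrics, resolve_binary, Binary
from .coverage import assign_coverage, coverage_index
from .grid import build_grid
from .landscape import generate_host_trees, generate_roads, make_front_occupancy, place_nests
from .rng import substream_seed
from .survey import DetectionConfig, Status, field_survey, imagery_survey
from .types import Extent

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "coverage_outcome",
    "chi_square_association",
    "DEFAULT_BINS",
]

SCHEMA_VERSION = 1

# decile bins for the coverage-outcome table
DEFAULT_BINS = [i / 10 for i in range(11)]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated survey campaign (all lengths in km)."""

    schema_version: int = SCHEMA_VERSION
    # extent
    width: float = 22.0
    height: float = 22.0
    # roads
    road_density: float = 1.5
    n_towns: int = 3
    # street-imagery coverage
    coverage_base_p: float = 0.35
    coverage_town_boost: float = 0.5
    coverage_town_range: float = 3.0
    # host trees
    tree_base_intensity: float = 1.5
    roadside_multiplier: float = 5.0
    roadside_band: float = 0.05
    cluster_sd: float = 0.05
    mean_cluster_size: float = 4.0
    # occupancy front (west = colonised)
    front_position: float = 11.0
    front_width: float = 8.0
    p_behind: float = 0.5
    p_ahead: float = 0.05
    aggregation_range: float = 1.0
    # protocols
    field_detect_radius: float = 0.3
    field_p_detect: float = 1.0
    imagery_detect_radius: float = 0.1
    imagery_clear_radius: float = 0.05
    imagery_p_detect: float = 0.95
    respect_season: bool = False
    # rasterization
    raster_resolution: float = 0.25

    @property
    def extent(self) -> Extent:
        return Extent(0.0, 0.0, self.width, self.height)

    def field_config(self) -> DetectionConfig:
        return DetectionConfig(
            detect_radius=self.field_detect_radius,
            clear_radius=self.field_detect_radius,
            p_detect=self.field_p_detect,
        )

    def imagery_config(self) -> DetectionConfig:
        return DetectionConfig(
            detect_radius=self.imagery_detect_radius,
            clear_radius=self.imagery_clear_radius,
            p_detect=self.imagery_p_detect,
            respect_season=self.respect_season,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(cls)}
        for key in data:
            if key not in known:
                raise ValueError(f"unknown scenario config field: {key!r}")
        cfg = cls(**data)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"schema_version: expected {SCHEMA_VERSION}, got {cfg.schema_version}"
            )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def beauce_like() -> ScenarioConfig:
    """The default scenario (see module docstring)."""
    return ScenarioConfig()


@dataclass
class ScenarioResult:
    """One (grain, replicate) outcome of an experiment."""

    grain: float
    seed: int
    cm: ConfusionMatrix
    metrics: AgreementMetrics
    table: pd.DataFrame = field(repr=False)  # cell_id, field_status, imagery_status, coverage_index


def _simulate_landscape(config: ScenarioConfig, seed: int):
    extent = config.extent
    network = generate_roads(extent, config.road_density, config.n_towns, seed)
    assign_coverage(
        network,
        base_p=config.coverage_base_p,
        town_boost=config.coverage_town_boost,
        town_range=config.coverage_town_range,
        seed=seed,
    )
    trees = generate_host_trees(
        network,
        extent,
        base_intensity=config.tree_base_intensity,
        roadside_multiplier=config.roadside_multiplier,
        roadside_band=config.roadside_band,
        cluster_sd=config.cluster_sd,
        mean_cluster_size=config.mean_cluster_size,
        seed=seed,
    )
    occ = make_front_occupancy(
        extent,
        front_position=config.front_position,
        front_width=config.front_width,
        p_behind=config.p_behind,
        p_ahead=config.p_ahead,
    )
    nests = place_nests(trees, occ, config.aggregation_range, seed)
    return network, trees, nests


def run_scenario(
    config: ScenarioConfig,
    grains: Sequence[float],
    n_replicates: int,
    seed: int,
    replicate_seeds: Sequence[int] | None = None,
) -> list[ScenarioResult]:
    """Run the paired multi-grain experiment.

    One landscape realisation per replicate, surveyed at every grain in
    ``grains``; returns one ScenarioResult per (grain, replicate), in
    replicate-major order.  Replicate seeds derive from ``seed`` via the
    substream rule unless ``replicate_seeds`` lists them explicitly.
    """
    if not grains or any(g <= 0 for g in grains):
        raise ValueError("grains must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if replicate_seeds is not None and len(replicate_seeds) != n_replicates:
        raise ValueError("replicate_seeds must have one entry per replicate")
    results = []
    for r in range(n_replicates):
        if replicate_seeds is not None:
            rep_seed = int(replicate_seeds[r])
        else:
            rep_seed = substream_seed(seed, f"replicate-{r}")
        network, _, nests = _simulate_landscape(config, rep_seed)
        for grain in grains:
            grid = build_grid(config.extent, grain)
            f_stat = field_survey(
                grid, nests, network, config.field_config(), seed=rep_seed
            )
            i_stat = imagery_survey(
                grid, nests, network, config.imagery_config(), seed=rep_seed
            )
            cm = confusion(f_stat, i_stat)
            cov = {
                c.id: coverage_index(c, network, config.raster_resolution).value
                for c in grid.cells
            }
            table = pd.DataFrame(
                {
                    "cell_id": [c.cell_id for c in f_stat],
                    "field_status": [c.status.value for c in f_stat],
                    "imagery_status": [c.status.value for c in i_stat],
                    "coverage_index": [cov[c.cell_id] for c in f_stat],
                }
            )
            results.append(
                ScenarioResult(
                    grain=grain, seed=rep_seed, cm=cm, metrics=metrics(cm), table=table
                )
            )
    return results


_OUTCOMES = ("TP", "FP", "FN", "TN")


def _outcome(field_status: str, imagery_status: str) -> str | None:
    pred = resolve_binary(Status(imagery_status))
    if pred is Binary.EXCLUDED:
        return None
    truth_pos = Status(field_status) is Status.PRESENCE
    pred_pos = pred is Binary.POSITIVE
    if truth_pos:
        return "TP" if pred_pos else "FN"
    return "FP" if pred_pos else "TN"


def coverage_outcome(
    result: ScenarioResult, bins: Sequence[float] = DEFAULT_BINS
) -> pd.DataFrame:
    """Counts of TP/FP/FN/TN per coverage-index bin for one result.

    ``bins`` are strictly increasing breakpoints spanning [0, 1]; bin i
    is [bins[i], bins[i+1]), the last closed at 1.  Excluded (NO_DATA)
    cells do not appear; if nothing remains the table is empty (with a
    warning).
    """
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be strictly increasing")
    if bins[0] > 0 or bins[-1] < 1:
        raise ValueError("bins must span [0, 1]")
    rows = []
    for _, row in result.table.iterrows():
        out = _outcome(row["field_status"], row["imagery_status"])
        if out is None:
            continue
        rows.append((float(row["coverage_index"]), out))
    cols = {
        "bin_lo": [], "bin_hi": [], "TP": [], "FP": [], "FN": [], "TN": []
    }
    if not rows:
        warnings.warn("no analyzed cells; coverage-outcome table is empty", stacklevel=2)
        return pd.DataFrame(cols)
    vals = np.array([v for v, _ in rows])
    # right-open bins, top bin closed at the last breakpoint
    idx = np.clip(np.digitize(vals, bins[1:-1], right=False), 0, len(bins) - 2)
    for b in range(len(bins) - 1):
        cols["bin_lo"].append(bins[b])
        cols["bin_hi"].append(bins[b + 1])
        for o in _OUTCOMES:
            cols[o].append(sum(1 for i, (_, out) in zip(idx, rows) if i == b and out == o))
    return pd.DataFrame(cols)


def chi_square_association(table: pd.DataFrame) -> float:
    """Pearson chi-square statistic of the bin x outcome contingency table.

    Computed by the direct formula sum((O - E)^2 / E) with
    E = row_total * col_total / grand_total; all-zero rows and columns
    contribute nothing.  Descriptive only — no sampling distribution is
    attached.
    """
    counts = table[list(_OUTCOMES)].to_numpy(dtype=float)
    counts = counts[counts.sum(axis=1) > 0][:, :]
    if counts.size == 0:
        return 0.0
    counts = counts[:, counts.sum(axis=0) > 0]
    grand = counts.sum()
    if grand == 0:
        return 0.0
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())
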