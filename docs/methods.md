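# Methods

## The survey model

A landscape carries a set of nest sites (host trees with ≥1 winter
nest). Two protocols read it through a square sampling grid of mesh
*g* km:

- **Field protocol.** Crews drive every road. A nest within
  `detect_radius` (default 0.3 km — eye plus binoculars) of any road is
  detected with probability `p_detect` (default 1); a detection makes
  the nest's cell `PRESENCE`, otherwise the cell is `ABSENCE` once all
  roads are driven. The field survey can never return `NO_DATA` (any
  road is drivable) and never `INDISTINCT` (binoculars resolve doubt).
- **Imagery protocol.** A virtual operator sees only road segments
  flagged as present in the imagery database (optionally only those
  photographed in winter, when nests are conspicuous). A cell with no
  observable road at all is `NO_DATA`. A detected nest within
  `clear_radius` (default 0.05 km) is unambiguous → `PRESENCE`;
  detections only in the marginal band (`clear_radius`,
  `detect_radius`] (default 0.1 km) leave a persistent doubt →
  `INDISTINCT`; otherwise `ABSENCE`. Defaults `p_detect` = 0.95.

Detection is a distance-thresholded Bernoulli per nest, independent
across nests, using the nest's distance to the nearest *observable*
road of the whole network; the detection is credited to the cell
containing the nest (the sighting road may sit just across a cell
boundary, as with real georeferenced roadside records — `NO_DATA` is
still decided from the roads intersecting the cell itself). The
distance radii and `p_detect` are scenario knobs, not measured
quantities; panoramic-imagery sighting distances are unknown, so any
quantitative sensitivity claim should be read conditional on them (re-run
`analysis/04_scale_experiment.py` with a modified `ScenarioConfig` to
probe them).

Because detection applies only to true nests and the field protocol
detects with certainty over a radius at least as wide as the imagery
protocol's, an imagery `PRESENCE` implies a field `PRESENCE`: false
positives are structurally impossible under the defaults. The empirical
FP = 0 / specificity = 1 outcome in every simulated replicate is a
consequence of the model, not a tuned result.

## Agreement statistics

Imagery statuses collapse to binary: `PRESENCE` → positive,
`ABSENCE` and `INDISTINCT` → negative, `NO_DATA` → excluded from the
analysis. Counts over analyzed cells give TP, FP, FN, TN and
sensitivity TP/P, specificity TN/N, accuracy (TP+TN)/(P+N), and the
Matthews/phi correlation. Conventions: report rounding is half-up to 3
decimals (internal values full precision); a zero MCC denominator
yields 0 with a warning; P = 0 or N = 0 makes sensitivity or
specificity NaN with a warning rather than an arbitrary number; a field
status outside {PRESENCE, ABSENCE} is an input error, never silently
dropped.

## Synthetic landscapes

All lengths are planar km, origin at the extent's SW corner.

- **Roads.** Town centres uniform; straight connector polylines join
  each town to its nearest predecessor (within a length budget); the
  residual budget is spent on 1 km street sticks whose centres are a
  60/40 mixture of Gaussian-around-a-town (sd = 15 % of the short
  extent side) and uniform. The Poisson street count makes the expected
  total length exactly `density × area`. Default density 1.5 km/km²
  (rural-plain order of magnitude), 3 towns in 22 × 22 km.
- **Imagery coverage.** Per-segment Bernoulli with probability
  `base_p + town_boost · exp(−d/town_range)` clamped to [0, 1], d =
  midpoint distance to the nearest town. Defaults 0.35 + 0.5 ·
  exp(−d/3): roughly half the segments covered overall and near-town
  segments almost saturated — the urban bias of real imagery fleets.
- **Host trees.** Thomas cluster process: Poisson parents of intensity
  `base_intensity / mean_cluster_size`, multiplied by
  `roadside_multiplier` within `roadside_band` of a road (simulated by
  thinning at the band maximum), Gaussian offspring (sd `cluster_sd`).
  Defaults: 1.5 trees/km², multiplier 5 over a 0.05 km band, clusters
  of mean 4 with sd 0.05 km. The multiplier is a scenario choice — no
  quantitative edge-effect magnitude is available to calibrate it.
- **Occupancy front.** Logistic along x from `p_behind` (0.5, colonised
  west) to `p_ahead` (0.05, invasion front east), midpoint at
  `front_position` (11 km), transition scale `front_width`/4 (8 km
  width); zero width degenerates to a step.
- **Nest aggregation.** Each tree keeps a nest iff Φ(z) < occ(x, y),
  where z is a unit-variance smoothed Gaussian white-noise field
  (kernel sd = `aggregation_range`/2, default 1 km) sampled at the
  nearest lattice node. The lattice is padded by the kernel support and
  the field standardised by the exact (truncated-kernel) variance, so z
  is exactly N(0, 1) and the marginal nest probability equals the
  occupancy surface exactly — aggregation costs no calibration. Range 0
  gives independent thinning. Nest counts are 1 + Poisson(1).

What the generator does **not** emulate: real road topology and
connectivity, host-species composition, multi-year nest persistence and
accumulation, adaptive neighbour-cell prospecting, operator behaviour
(zoom, viewing angle), and imagery acquisition dates beyond a binary
winter/other season flag. Passing tests therefore certify the survey
*machinery* and the qualitative scale/coverage mechanisms, not any
quantitative claim about a particular real landscape.

## Grids, rasterization, numerics

- Cells are half-open squares `[x0, x0+g) × [y0, y0+g)`, ids row-major
  from the SW corner; boundary points belong to the higher-index cell.
  This is the single coordinate convention of the package.
- Coverage rasterization: pixels (default 0.25 km) anchored at each
  cell's SW corner; a non-divisible resolution truncates the last
  row/column at the cell boundary. Pixel membership is closed-square
  intersection — a road running along a pixel edge (or touching only a
  corner) marks the pixel; deterministic and orientation-independent.
  The per-cell coverage index is covered-road pixels over *all* pixels
  of the cell; the covered-over-road-pixels variant is provided
  separately (`road_fraction_covered`) but is not the canonical index.
  Whether real grids anchor pixels per cell or globally is survey-
  specific; per-cell anchoring is assumed here.
- Seeding: every stage draws from
  `SeedSequence(seed, spawn_key=(crc32(stage_name),))`; replicate seeds
  of experiments derive the same way from the master seed unless given
  explicitly. Fixed seeds reproduce outputs byte-for-byte.

## Experiment design and problem sizes

The default `beauce_like` scenario is a 22 × 22 km window; experiments
reuse one landscape realisation per replicate across all grains (paired
design, isolating the grain effect), with 50 replicates at grains
16/8/4/2 km as the standard run — sized so a full experiment completes
in about a minute and a half on one CPU while leaving the paired
sensitivity comparison well resolved. The coverage-outcome table bins
analyzed cells by coverage index (default deciles; the bin edges are
user-specifiable) and counts TP/FP/FN/TN per bin; the attached
chi-square statistic is descriptive only.

## Known limitations

- At a 16 km grain over a 22 km window only 4 cells exist, so
  grain-16 sensitivity takes coarse values and negatives may be absent
  (specificity then NaN); conclusions at that grain lean on the paired
  replication.
- The road generator guarantees density and town bias, not network
  connectivity; no routing is possible on it.
- `INDISTINCT` is operationalised purely by the marginal-distance band;
  real doubt also involves image quality and season, which the model
  folds into `p_detect` and the season flag.
- Confidence intervals for the agreement statistics are not provided;
  replicate spread in experiments is the intended uncertainty measure.
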