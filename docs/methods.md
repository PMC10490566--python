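# Methods

This note documents the models, estimators, parameters and numerical
choices behind `mabumat`, and what the synthetic-data generator does and
does not emulate.

## Sensing model and coordinate conventions

The sensing surface is modelled as an `n_rows × n_cols` grid of
piezoresistive cells read at `bit_depth` bits.  The default configuration
realises 924 cells over a 1000 × 500 mm mat as 22 rows × 42 columns
(22 · 42 = 924) at 12 bits; the grid factorisation is a package choice — any
factorisation can be configured, and all geometry derives from
`length_mm / n_cols` and `width_mm / n_rows`.

Coordinates are millimetres on the mat: x along the 1000 mm axis increasing
left→right from the practitioner's perspective, y along the 500 mm axis
increasing posterior→anterior.  Cell (r, c) is centred at
((c + ½)·pitch_x, (r + ½)·pitch_y).  This convention makes left/right
mirroring an exact symmetry (x ↦ length − x), which the tests exploit.

## Filtering and segmentation

The high-pass filter zeroes every cell strictly below β and leaves the rest
untouched.  Hard zeroing (rather than soft attenuation) was chosen because
the threshold's purpose is to subtract the static preload of the mat's foam
layers and the sensor noise floor — signal below β carries no postural
information.  β defaults to 81.9 raw units (2 % of 12-bit full scale) and is
configurable.  The filter is idempotent and monotone in β.

Segmentation assigns columns [0, n_cols/2) to the left-foot matrix and the
rest to the right-foot matrix (the extra column of an odd count goes right).
This half-split matches the use case: the stance is static and wide, with
one foot per half.  Multi-blob tracking across the midline is out of scope.

## Centers of pressure

All COPs are pressure-weighted centroids of cell-center coordinates — the
standard baropodometric definition.  The overall COP decomposes exactly
over the halves, COPo = (Pl·COPl + Pr·COPr)/(Pl + Pr), which serves as an
internal consistency oracle (tested to 1e-9 mm).  A frame with zero total
pressure has no COP and raises an error rather than returning a sentinel.

## Foot geometry estimators

`detect_foot` first removes residual speckle: 8-connected components of
loaded cells carrying less than 5 % of the strongest component's load are
discarded.  This matters because a filtered foot is *two* disconnected
components (heel and forefoot hotspots), so the rule keeps every
substantial component rather than only the largest one.

- **Toe-out angle** — the principal axis of the pressure-weighted second
  central moments of the blob, i.e. the image-moments orientation
  estimator.  The 180° axis ambiguity is resolved by orienting the axis
  with a positive anterior component; the angle from the anterior axis is
  reported outward-positive per side (toes toward −x is outward for the
  left foot, toward +x for the right).  Blobs with fewer than three loaded
  cells or with a vanishing minor moment (collinear) are rejected.
- **Heel/forefoot split** — load fractions on either side of the
  perpendicular bisector of the blob's extent along the principal axis.
  The boundary is anchored at the extent midpoint, not the centroid: the
  centroid migrates into the heavier lobe under uneven loading, which
  would bias the estimate toward ½ and can never report a fully
  heel-loaded foot; the extent midpoint stays between the lobes.
- **Stance metrics** — stance width is the Euclidean distance between foot
  centroids; center-line offsets are |centroid_y − width/2|; the
  left/right balance is |Pl − Pr|/(Pl + Pr), dimensionless in [0, 1] and
  invariant to uniform scaling of all pressures (hence to body weight).

## Entry criteria and calibration

Five criteria gate entry into training, with defaults chosen as sensible
tuning values (they are configuration, not measured constants):

| criterion | threshold (default) |
|---|---|
| left/right balance | ≤ 0.15 |
| center-line offset, each foot | ≤ 40 mm |
| stance width | ≥ 400 mm (proxy for "wider than shoulder width") |
| toe-out angle, each foot | within [0°, 45°] |
| heel/fore imbalance, each foot | ≤ 0.30 |

The toe-out range's bounds are the stance's defining rotation criterion;
the other thresholds have no canonical values and are exposed in the
config.  Validation is scale-invariant in body weight, and loosening any
single threshold can only turn failures into passes (monotonicity, tested).

Calibration captures the three reference COPs (overall, left, right), the
detected foot geometry and the region radius α from a single validated
frame; an invalid stance raises a redo-calibration error carrying the
per-criterion report.  α defaults to 40 mm — in the deployed system this
radius is tuned per pilot data; here it is an explicit parameter.  An
N-frame averaging window is deliberately not implemented: a single frame
keeps the profile deterministic and the monitor's self-consistency exact
(the calibration frame itself always assesses as good).

## Monitoring and the session state machine

The good/poor test applies strict per-axis bounds
(ref − α < value < ref + α on x and y) to each of the three COPs.  The
per-axis (box) form is the primary definition; a Euclidean (circle) mode is
selectable, and the circle region is strictly contained in the box at equal
α, so circle mode is the more conservative classifier.  A displacement of
exactly α falls outside in both modes.  Beyond the COP regions, flags are
raised for foot-centroid drift > 50 mm, a toe angle leaving [0°, 45°] or
drifting > 15° from its calibrated value, and left/right balance exceeding
its threshold.  The drift thresholds are package defaults, configurable.

The normalised displacement d = max over the three COPs of the per-region
displacement drives the four feedback bands: balanced (d ≤ 0.4), slight
(0.4 < d ≤ 0.75), severe (0.75 < d < 1), broken (d ≥ 1).  Band edges are
configurable; the broken band coincides exactly with region exit, so a
"broken" severity always implies a poor frame.

The session machine counts held time as (good frames)/fps — integer frame
counting avoids floating-point drift, so 600 good frames at 20 fps is
exactly 30 s.  The first poor frame (after a configurable debounce count,
default 1: the deployed behaviour is an immediate stop) freezes the timer,
records the break time and terminal flags, computes the final level/group
and emits a notification event; the broken state is terminal.  A stream
that ends before any frame passes the entry gate yields an aborted session.
The sound notification of the deployed system is realised as a log event.
Event logs are JSONL with sorted keys, so identical streams produce
byte-identical logs.

## Reward mechanics

One level per full 10 s held (floor convention: exactly 10.0 s awards
Level 1), groups beginner/intermediate/veteran/expert at levels 0–6, 7–12,
13–18 and ≥ 19.  The leaderboard sorts by duration descending with earlier
recordings winning ties, and a returning participant keeps only their best
run — tie and duplicate policies are package choices.

## The synthetic-stance generator

Each foot is two anisotropic Gaussian pressure lobes (heel, forefoot)
centred ±80 mm along the foot's long axis, the axis rotated outward by the
toe angle.  Lobe spreads are σ_along = 24 mm and σ_across = 20 mm (heel) /
26 mm (forefoot); the 160 mm lobe separation with these spreads keeps the
lobes distinct enough that the heel/fore estimator can recover the imposed
lobe loading within a few percent up to 75/25 splits.  Amplitudes are
bivariate-normal normalised so each lobe integrates to its mass share; the
field is scaled to a total of 680 raw units per kilogram (an 80 kg subject
peaks near 60 % of full scale, leaving headroom against saturation), then
additive truncated-Gaussian noise is applied and the field is quantised to
the sensor's bit depth.

Leaning is imposed the way a standing human leans — by load redistribution,
not foot movement: a medio-lateral lean shifts weight between the feet
(Δw = −lean_x/stance_width), an antero-posterior lean shifts each foot's
heel/fore share (Δf = lean_y/(160·cos φ)).  COP displacement therefore
tracks the lean vector while foot centroids stay nearly fixed, which is
what lets the monitor distinguish leaning from foot shifting.

Ground-truth COP labels are measured on the noise-free quantised field —
exactly what an ideal sensor would report — while toe angles and load
splits are the imposed parameters.  The ground-truth stance width is the
distance between the noise-free per-foot COPs; note this is smaller than
the foot-center distance when the load rides fore or aft, because each
foot's COP moves along its own axis.

Scripted sessions hold the stance with postural sway modelled as a
per-axis AR(1) mean-reverting walk (stationary amplitude 8 mm, timescale
1 s by default — small against α = 40 mm), preceded by a settling phase in
which the simulated practitioner widens into the stance (those frames fail
the width gate, so the monitor's training clock starts exactly at the
scripted time).  At the scripted break time one of three trajectories runs:
`lean_out` jumps to a 60 mm lateral lean (1.5 α, a sudden balance loss) and
ramps to 120 mm, `foot_shift` slides the right foot 80 mm, and `rise`
unloads 35 % of the weight into the forefeet (standing up out of the
squat).  The lean-out direction is kept within ±30° of the lateral axis: a
large sagittal lean would move each foot's own COP far enough along its
axis to alias a foot shift.

Three-condition cohorts (no feedback / clock / game feedback) draw held
durations log-normally — positive and right-skewed, as hold times are —
with default medians 40 s, 55 s and 80 s and log-σ 0.45.  The ordering
encodes the designed effect (game feedback > clock > none); the magnitudes
are generator defaults for a clearly detectable effect at 14 participants
per arm, not measured values.

**What the simulator does not emulate:** anatomical sole shapes (arch, toe
prints), sensor cross-talk and hysteresis, spatially correlated noise,
fatigue drift, multi-segment sway dynamics, or feet crossing the mat's
midline.  Passing tests show the pipeline recovers the parameters of this
idealised model; accuracy on real mats — where blob shape and noise are
richer — must be established against recorded data.

## Numerical choices and edge cases

- Strict inequalities throughout the region tests; d = 1 exactly is
  outside.
- Exact integer accumulation for totals and held frames; COP arithmetic in
  double precision (composition identity holds to 1e-9 mm).
- Degenerate blobs (< 3 loaded cells, collinear) raise typed errors; a
  vanished foot during streaming is treated as a foot-position break
  rather than a crash.
- The rank-sum test computes U from midranks.  Exact p-values use the
  classical rank-sum counting recursion when the pooled sample is
  tie-free and full enumeration of C(N, n₁) assignments otherwise;
  the automatic method switches to a tie-corrected normal approximation
  with continuity correction above N = 12, and `method="exact"` forces
  enumeration (used by the type-I calibration suite at n = (7, 7)).
  Two-sided p doubles the smaller one-sided tail, capped at 1.
- Quartiles use linear interpolation; outliers follow the 1.5·IQR rule.
- Heat maps are plain (P2) PGM at the sensor's full-scale maxval — a
  lossless text round-trip.

## Problem sizes

The default suites use 50 stances for parameter recovery, 100 scripted
sessions (break times 4–9 s at 20 fps) for break detection, 10,000 random
triples for region semantics, 1,000 frames for the COP oracle, 2,000 null
replicates for type-I calibration and 100 cohort replicates for the
feedback comparison — sizes chosen to give stable statistics on a desktop
run.

## Known limitations

- The orientation estimator degrades when sensor noise approaches β
  itself (2 % of full scale): surviving noise adjacent to the blob merges
  with it and can bias the principal axis by several degrees.  Recovery
  guarantees are stated for noise up to 1 % of full scale — a functioning
  mat keeps its noise floor well below the preload threshold.
- One foot per mat half is assumed; stances with crossed or centred feet
  are out of scope.
- The box-region default and all drift thresholds are design parameters;
  deployments should tune them against pilot recordings.
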