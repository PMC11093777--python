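# Methods

## Model

All computation happens in 2-D axial frames, one per placement level per
ankle. The canonical frame puts the origin at the level's lateral fibular
entry point, +x along the femoral epicondylar axis (lateral → medial) and +y
anterior. A screw axis is the infinite in-plane line through the entry point
whose direction is the epicondylar axis rotated counter-clockwise by the
trajectory angle — the posterior-to-anterior opening convention; angles must
lie strictly in (0°, 90°). The axis is not truncated at bone boundaries:
proximity is measured to the full line, matching how axis lines are drawn
across an axial slice.

Proximity is the perpendicular distance from the artery's centerline point
to the axis (`|cross(direction, artery − anchor)|` for a unit direction).
Injury potential is `distance ≤ diameter/2`, boundary inclusive; the
diameter whitelist defaults to {3.5, 4.0, 4.5} mm and is configurable for
non-standard hardware. Because all three diameters share one axis per
(level, rule), threshold nesting — a 3.5 mm flag implies a 4.0 mm flag
implies a 4.5 mm flag — is structural, not statistical.

Working on the artery centerline rather than the lumen edge, and in 2-D
rather than along a 3-D vessel course, are modelling choices: the measured
quantity is the in-slice axis-to-centerline distance, which is what the
radius thresholds are defined against.

## Synthetic anatomy

The generator emulates only the sufficient statistics the analysis consumes,
not images or 3-D morphology. Per ankle and level it draws:

* **Individual screw angle** ~ Normal(mean_h, sd_h) truncated to (0°, 90°)
  by rejection. Default means rise from 29.42° (0.5 cm) to 41.97° (5 cm)
  with SDs of 6.3–7.3°; at these parameters the truncation is essentially
  inactive (rejection < 1 %), so the realized SD tracks the configured SD.
  The two-case reading of the individual angle (incisura-perpendicular at
  ≤ 3 cm, interosseous-parallel above) is carried as an `incisura_visible`
  flag; both cases reduce to reading the stored direction.
* **Artery position** = `entry + a·u(20°) + s·n(20°)`, where `u(20°)` is the
  20° corridor direction, `n` its in-plane normal, `a` a fixed along-corridor
  distance (default 4 mm) and `s` ~ Normal(mean_h, sd_h) the signed
  perpendicular offset. The 20° line is the reference corridor because it is
  the calibration arm. Geometrically the distance from the artery to a
  corridor at angle θ is `|s·cos(θ−20°) − a·sin(θ−20°)|`, so steeper
  trajectories sweep toward the artery — reproducing the qualitative finding
  that individual-angle trajectories carry the highest proximal risk.

Draws are rejected until the artery keeps `min_clearance_mm` from the whole
corridor fan at that level (the 20° and 30° lines and the ankle's own
individual axis). The fan-wide clearance — rather than clearance from a
single reference line — is what makes a hard safety margin meaningful: with
clearance above the largest screw radius, *no* simulated screw at that level
can flag, for any rule or diameter, for any seed. The packaged default sets
2.5 mm clearance at 0.5 and 1 cm for exactly this purpose. Rejection
fractions are counted and logged; the default configuration rejects ≈ 9 % of
artery draws overall.

Randomness: one root seed, per-ankle substreams spawned via
`numpy.random.SeedSequence.spawn`, so a cohort is bitwise reproducible and
any prefix of it is independent of later ankles.

## Calibration

`calibrate_artery_means` adjusts each level's mean offset by bisection so
that the Monte-Carlo flag rate of a chosen (angle, diameter) arm — default
20°/3.5 mm — hits a target proportion within ±0.03 at n = 5000 draws. The
evaluation mimics the generator's conditional law (fan-clearance rejection
included) and is vectorised; the flag rate is monotone decreasing in the
mean offset, so bisection over [0, 30] mm converges. Levels with target 0
skip the solve and instead receive `min_clearance = diameter/2 + 0.75 mm`
(2.5 mm for the 3.5 mm arm), which also clears the largest default screw
radius of 2.25 mm, plus a mean offset four SDs above the clearance to keep
rejection cheap. Unreachable targets raise a calibration error naming the
level.

The packaged `default_cohort.json` was produced by calibrating the default
anatomy against the per-level 20°/3.5 mm rate column
(0, 0, 7, 32, 42, 42, 45, 40, 39, 43 % for levels 0.5 … 5 cm) and freezing
the resulting offsets (7.3, 7.3, 3.46, 2.15, 1.79, 1.80, 1.70, 1.91, 1.93,
1.80 mm). Offset SD defaults to 1.2 mm at every level — a plausible
between-subject spread for a peri-fibular vessel position — and is the one
generator parameter not pinned by a published number.

## Statistics

Cell tables count flags exactly per (level, rule, diameter); percentages are
kept at full precision and rounded only for display (one decimal, half-up).
Marginals are sums over the other two axes and assert conservation of both
flagged and total counts at write time.

Group comparison is the Pearson chi-square test on the k×2
flagged/not-flagged table (`scipy.stats.chi2_contingency` without continuity
correction, matching the named test), df = k−1. A table whose flagged column
is all zero is degenerate — proportions identical by construction — and
returns statistic 0, p = 1. Expected counts below 5 warn but do not block.

The homogeneous-subset letters use all pairwise 2×2 Pearson tests with
Bonferroni adjustment over the number of pairs (the SPSS column-proportions
convention; the source analysis reports only letters, so the post-hoc
procedure is a documented convention here, with alpha and adjustment
configurable). The non-significance graph's maximal cliques, lettered in
order of their first category, give a compact letter display with the exact
defining property: two categories share a letter iff their adjusted pairwise
comparison is non-significant. With ≤ 10 categories the clique enumeration
is trivial.

## Problem sizes and tolerances

The test suite simulates cohorts of 5–1000 ankles (0.09 s per 100 ankles for
the full 90-option grid) and checks the calibrated 20°/3.5 mm column at
n = 1000 ankles within ±5 percentage points — generous against the ≈1.6-point
binomial standard error at that size plus the ±3-point calibration
tolerance. Monte-Carlo distribution checks use n = 20 000 single-level
ankles and 3-standard-error bands. Distance geometry is verified against a
coarse-to-fine brute-force line search (1e-6 mm) and under random rigid
transforms of the frame (1e-9 mm).

## Known limitations

* The generator reproduces per-level marginal structure of the calibration
  arm; the full joint structure across rules and diameters of a real cohort
  (e.g. the distal reversal where individual angles are *safer* below
  2.5 cm) is only qualitatively, not quantitatively, matched.
* Artery position is modelled per level independently within an ankle; real
  vessel courses are longitudinally correlated, so per-ankle risk profiles
  are smoother in reality than in synthesis.
* Trauma-displaced artery positions are out of scope, as is any image-level
  modelling (DICOM, segmentation, centerline tracking).
* Laterality is not modelled: every anatomy is an independent ankle.
* The chi-square p-values are asymptotic; cells with tiny expected counts
  (sparse user tables) carry a warning rather than an exact-test fallback.
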