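# Methods

## Observational model

One deployment observes a single settlement-stage larva in a circular
chamber (21 cm diameter) drifting at ~5 m depth, photographed from below at
5-second intervals over a 15-minute window (nominally 180 frames). Each
frame records the larva's pixel position and the compass bearing of the
image-top direction from the instrument's digital compass. The chamber
drifts with the water mass and rotates slowly, so the larva's position in
the image mixes its behavior with the chamber's rotation; converting
positions to world-frame bearings through the per-frame compass heading
removes the rotation.

### Geometry and sign conventions

Positions are converted to polar coordinates about the chamber center
(default 1296, 972 — the center of a 5-megapixel 2592 × 1944 frame; image y
grows downward). Because the camera looks upward, the image is mirrored:
by default the x axis is flipped about the center before polar conversion
(`mirror=True`), and the cardinal bearing of the larva is
`(angle_chamber + heading_top) mod 360` (`compose="add"`). The original
digitizing software's convention is not recoverable, so both the mirror
flag and the composition sign are configurable; the defaults are the unique
pair under which a simulated larva holding a fixed world bearing
round-trips exactly through the pipeline, and every output table carries
the flags used. The conventions cancel in r (which is invariant to adding
any constant to all angles) and affect only the sign convention of mean
bearings.

Dropped compass readings are filled by linear interpolation on the
unwrapped heading series (heading is a smooth instrument signal); missing
larva positions are never interpolated — those frames are dropped. Frames
inside a configurable acclimation window at the start of a track are
excluded (default 0 s: tracks are assumed to begin at the observation
window; the field protocol's 5-minute acclimation precedes it).

## Circular statistics

All angles are degrees clockwise from true North in [0, 360); radians are
internal. For a sample θ₁…θₙ, C and S are the mean cosine and sine, the
mean direction is atan2(S, C) and r = √(C²+S²). When r is numerically zero
the mean is undefined; 0° is reported with a validity flag rather than an
error, to keep pipelines total.

**Rayleigh test.** The analytic p-value uses the classical second-order
series approximation in Z = n r²:

    p = e^(−Z) [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],

clipped to [0, 1]. It agrees with an independent implementation (pingouin's
Zar-style approximation) to a few 10⁻³ and with a 19 999-draw permutation
reference to well within 0.02 over n ∈ {10, 30, 180}. Below n = 10 the
analytic result is flagged and the permutation method (uniform resampling
of n angles, add-one p, mandatory seed, ≥ 999 draws) is recommended. Which
method the pipeline uses is a config switch (`rayleigh_method`), defaulting
to analytic.

Positions 5 s apart are serially dependent, so within-run p-values are
anti-conservative in an absolute sense; the analysis treats them
comparatively (the same caveat applies to the original instrument's
processing), and reports note it. The simulator's noise is i.i.d. von Mises
per frame to match the test's assumption; an AR(1)-on-angles switch
(`ar1_rho`) exists to study the caveat explicitly.

**Wallraff dispersion test.** Each group's members are reduced to absolute
angular deviations (shorter arc, in [0, 180°]) from that group's own
circular mean; deviations are compared with a two-sided rank-sum test for
two groups or Kruskal-Wallis for more. Relabelling groups leaves p
unchanged.

**von Mises utilities.** Sampling uses the generator's von Mises draws
(κ = 0 is uniform); fitting takes μ as the circular mean and solves
A(κ) = I₁(κ)/I₀(κ) = r from the Best–Fisher starting value with Newton
refinement. κ is capped at 10⁴ with a flag for degenerate samples; r = 0
returns κ = 0 with an undefined-mean flag.

**Circular confidence interval.** The population mean direction's 95% CI
uses the large-sample dispersion approximation: half-width
asin(z·σ̂) with σ̂² = (1 − α̂₂)/(2 n r²), α̂₂ the mean cosine of twice the
deviations from the mean; the interval degrades to ±180° (uninformative)
when the argument leaves the asin domain.

## Solar geometry

Sun azimuth/zenith come from the NOAA low-precision equations (fractional
year → equation of time and declination → hour angle → azimuth/zenith),
accurate to well under 0.5° of azimuth for 1950–2050 — far below the
10° bins used for orientation roses. Sunrise/sunset are the crossings of
zenith 90.833° (34′ refraction + 16′ solar semi-diameter); a geometric
(90°) convention is available (`sunrise_zenith`), and the two differ by
~4 minutes at the study site, immaterial to the regressions. All times are
UTC; longitude only brackets the civil date. The solar index of a
deployment is (t_mid − t_sunrise)/(t_sunset − t_sunrise) at the mean time
of its observation window: 0 at sunrise, 1 at sunset, affine in between;
values outside [0, 1] (deployment outside daylight) are returned for the
caller to flag rather than rejected.

## Screens and inclusion rules

- **Chamber-locked artifact**: flag when total unwrapped compass excursion
  ≥ 180° (both wrap crossings and direction reversals handled by
  unwrapping; "total excursion" rather than net rotation) AND
  r_chamber − r_card > 0.17 strictly. The 0.17 default sits in the trough
  of the bimodal r_chamber − r_card distribution observed in field data.
- **QC**: excluded when more than 3 vessels cruised nearby (boat traffic
  measurably increases directionality) or when a predator visibly
  interacted with the chamber (a manual annotation passed through as
  input).
- **Directional larva**: passes both screens and within-run Rayleigh
  p < α (default 0.05).
- **Across-run inclusion**: a species enters population-level tests with
  ≥ 30 individuals (default counted on tested individuals after screens;
  `basis="directional"` counts directional ones instead — both the
  threshold and the basis are configurable because the two published
  phrasings of the rule differ). Species below threshold are reported with
  an `insufficient_n` status, never silently dropped; at least 2
  directional larvae are additionally required for the test to be defined.

## Cues and covariates

- **Sun**: azimuth at the deployment's mean time and mean GPS position.
- **Coast**: great-circle (haversine) distance and initial bearing to the
  nearest digitized coastline vertex; ties broken by file order;
  coincident points give distance 0 with an undefined bearing.
- **Current**: the instrument's own drift (initial bearing and mean speed
  between first and last GPS fix) — the drogue locks it into the current,
  and the direction is "toward", i.e. the direction of travel.
- **Wind**: the meteorological station's "from" bearing by default; a
  `wind_toward` flag flips it 180°, making the (unstated) convention
  explicit.
- **Regressions**: within-run r is clipped to [10⁻⁶, 1 − 10⁻⁶],
  logit-transformed, and fitted by OLS against each covariate per species.
  The solar index is additionally fitted with a quadratic term (the sun's
  azimuth is easiest to judge when the sun is low, suggesting high r at
  both ends of the day); the quadratic model is reported alongside the
  linear one and its term's p-value lets callers apply the
  retain-if-significant rule. Shapiro residual normality is reported for
  significant models only. Multiple-testing correction (Benjamini-
  Hochberg) is applied within the pairwise species family only; across-run
  cue tests are reported unadjusted, as is conventional for such tables.

## Synthetic studies

The generator emulates the field campaign's conditions: site 43.69°N
7.31°E, deployment dates May 7 – July 27, observation windows of 180 frames
at 5 s placed uniformly over solar index 0.05–0.95 (daylight, as in the
field), instrument drift 0.2–0.4 m/s (bracketing the 25–35 cm/s
along-shore current) in a uniform direction, cloud cover Binomial(8, 0.35)
eighths, gamma wind speeds, Poisson(0.5) vessel counts (rare > 3
exclusions), 2% predator encounters, and standard lengths
N(10.5, 1.3²) mm — the covariate levels are plausible for the region and
produce QC exclusion rates similar to a real campaign. The chamber heading
follows a Gaussian random walk (step s.d. 3°/frame) plus a constant
rotation drift of 1°/frame: the drift turns the chamber ~180° per run, so
total excursions straddle the artifact screen's rotation threshold and both
screen branches are exercised. Radial position is Beta(5, 2) of the chamber
radius (larvae favor the wall); statistics use only angles.

Four strategies define ground truth: `fixed_bearing` (target bearing),
`sun_compass` (sun azimuth + offset, using the same ephemeris as the cue
module), `chamber_locked` (fixed chamber-frame angle) and `uniform_random`.
Observed chamber angles are the strategy target (transformed to the chamber
frame for world-referenced strategies) plus i.i.d. von Mises(0, κ) noise,
and pixel positions invert the default processing conventions exactly.
A master seed derives per-deployment integer sub-seeds; identical seeds
give byte-identical output files.

What the generator does **not** emulate: serial dependence of larva
positions (unless `ar1_rho` is set), swimming-speed constraints between
frames, depth behavior, cue interactions (e.g. cloud cover degrading the
sun signal), spatially realistic coastlines, or behavioral switching within
a run. Passing recovery tests therefore shows the pipeline's statistics are
correct under the stated model, not that real larvae satisfy that model.

One consequence of the study's geometry is worth stating: at 44°N in
summer the sun's azimuth spans only ~250° of the compass and is mostly
southerly, so a genuine sun-compass follower also shows residual cardinal
(southward) concentration, and a southward bearing-keeper shows residual
sun-relative concentration. Simulated recovery tests therefore discriminate
strategies by which reference gives the *higher* precision r and by
recovering the offset within the circular CI, not by expecting the other
reference to be exactly uniform.

## Numerical choices and degenerate inputs

- r = 0 (or below 10⁻¹²): mean bearing reported as 0° with a flag.
- Frames exactly at the chamber center: radius 0, angle undefined (NaN),
  dropped from bearing statistics.
- Mean bearings are wrapped to [0, 360); a rounding artifact that would
  produce exactly 360.0 maps to 0.0.
- Permutation p uses the add-one rule, so it is never exactly 0.
- κ fit: Newton iterations stop at |Δκ| < 10⁻¹⁰ or 25 iterations; κ ≥ 10⁴
  (or r within 10⁻¹² of 1) reports the cap with a flag.
- p-values are written to files at full precision; any rounding is left to
  display layers.

## Problem sizes used in validation

Calibration and recovery properties are checked at desk scale: Rayleigh
type-I error over 2000 uniform samples of n = 30; analytic-vs-permutation
agreement over 200 samples each of n ∈ {10, 30, 180} with 19 999
permutations; ground-truth recovery over 200 synthetic studies of 20
deployments each (κ = 2); artifact-screen sensitivity/specificity over 200
chamber-locked and 200 fixed-bearing deployments. These sizes give
Monte-Carlo standard errors comfortably below the acceptance bands they
are compared against.

## Command-line interface

`discorient` exposes `simulate`, `process`, `cues`, `analyze` and `report`
subcommands as thin wrappers over the library; settings come from a YAML
`RunConfig` that round-trips through serialization and is validated on
load. Exit code 0 on success, 2 on validation errors. Every exclusion is
logged with its deployment id and reason; retained + excluded equals the
input count, and output tables embed the convention flags under which they
were produced. Rose-diagram output is 10°-binned counts as CSV; rendering
is deliberately left to the user.

## Known limitations

- The within-run Rayleigh test ignores the serial correlation of positions
  (see above); its absolute p-values overstate significance.
- The nearest-coast cue uses coastline vertices, not interpolated
  segments; with a sparsely digitized coast the bearing can be biased
  toward vertices.
- The circular CI is a large-sample approximation; for very small
  directional counts it returns ±180° rather than pretending precision.
- The solar ephemeris is the low-precision NOAA model; it is not suitable
  for sub-arcminute work (and does not need to be here).
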