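# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `soartrack`. Units are SI unless stated; headings are
degrees clockwise from true north in [0, 360); altitudes are meters ASL
(above sea level) or AGL (above ground level, ASL minus terrain).

## Track model and preprocessing

A track is an ordered sequence of 1 Hz (nominally) GPS fixes. Times must be
strictly increasing; duplicate timestamps keep the first fix with a
warning. Sampling gaps longer than 3× the nominal interval split the track
into analysis blocks: kinematics, smoothing, and maneuver labels never span
a gap, and nothing is interpolated across one.

Positions are smoothed with a centered 3-point running mean per block
(endpoints keep raw values) to suppress high-frequency GPS jitter, then
differenced **forward** in time: interval *i* runs from fix *i* to fix
*i*+1, so maneuver boundaries align exactly with fix indices. Local
east/north displacements use an equirectangular projection about each
step's midpoint latitude; distances use the haversine formula on a
mean-radius sphere (R = 6 371 008.8 m). At soaring-flight step lengths
(≤ 40 m) the difference from full ellipsoid geodesics is micrometers —
far below GPS noise — so the spherical form is the default and an ellipsoid
library is deliberately not required. Vertical rate uses ASL differences so
terrain slope cannot masquerade as climb. Below a stillness floor of
0.5 m/s ground speed the heading is held from the previous interval and the
turn rate is zero, preventing jitter-driven fake turns at rest.

## Maneuver classification

Three maneuver classes, applied with precedence circles → glides →
residual:

**Circles.** A circle is a span accumulating a full turn and returning to
its starting heading within ±10°. Detection is a deterministic greedy
left-to-right scan over the signed turn rate: from an anchor interval,
wrapped heading differences are accumulated; the circle closes at the first
sample where |cumulative turn| lies in the closure band
[`full_turn_min` = 350°, 360° + 10°] **and** the heading has returned to
within ±10° of the anchor heading, with duration inside [8 s, 60 s]. Both
conditions are required, so an S-shaped meander can never close. The label
(`circle_cw` / `circle_ccw`) is the sign of the accumulated turn.

Three guards make the scan robust to wind drift. A circle flown at
airspeed T in wind W has a ground-heading wobble of amplitude
±asin(W/T) about the uniform air-frame rotation (±45° at W/T = 0.7); the
wobble cancels exactly at true closure because the motion is periodic.
Therefore (i) the cumulative turn may transiently overshoot the closure
band by up to `cum_overshoot_tol` = 160° before the scan aborts; (ii) the
scan aborts when the cumulative turn retreats more than
`turn_reversal_tol` = 135° from its running extreme — a genuine direction
reversal, which prevents a partial turn one way plus full turns the other
way from closing on net angle; (iii) the scan aborts early when almost no
turning has accumulated a quarter of the maximum duration in
(`turn_stall_deg` = 60°), which prevents a straight glide prefix from being
glued onto a following circle. The scan is O(n · max_duration) and has no
randomness; identical input and configuration give identical segmentations.

**Glides.** Straight flight: every sliding 20 s window inside the run must
have an (unwrapped) heading range ≤ 10° and no stationary interval. Windows
are evaluated fully inside each circle-free run, an interval is glide-
covered if *any* passing window covers it (robust to isolated noisy
windows), and a run shorter than the window can never be a glide. Each
maximal covered run becomes one segment, labeled `glide_up` when its mean
climb rate strictly exceeds 0.75 m/s — the climb needed to offset the
assumed still-air sink — else `glide_down`.

**Residual.** Remaining spans of moving flight at least 3 fixes long are
`meander` (heading-variable searching flight; no positive definition is
attempted); shorter or stationary spans, and spans inside data gaps, are
`unclassified`. The output is a sorted, non-overlapping, exhaustive
partition of the track's intervals; this is asserted on every
classification.

**Clusters.** Runs of ≥ 3 consecutive circle segments (no intervening
label) form circle clusters — the climbing sequences of the flight.

**Summary table.** Per-label statistics (count, mean duration, mean
altitude change, mean climb rate, mean ground speed, total time, percent of
time, net altitude change). Percentages use **classified time only**;
unclassified time is reported alongside. Circle "diameter" (2× mean
distance to centroid) is diagnostic output only and plays no role in
classification, because a drifting circle's ground-track extent mixes
airspeed geometry with wind drift.

## Airspeed and wind from circling

Ground velocity is the vector sum of air velocity (magnitude TAS) and
wind. Over one closed circle at constant airspeed the air-velocity integral
vanishes, so the time-weighted vector mean of ground velocity over the
circle equals the wind — exactly, with no model fit. Two numerical
corrections make the estimator accurate on sampled, imperfectly closed
circles:

- **Chord correction.** Forward differences measure chord speed, which
  understates arc speed by sin(x)/x with x = |turn rate|·Δt/2; per-interval
  speeds are multiplied by x/sin(x) (≈ 1.0034 at a 22 s period sampled at
  1 Hz). Exact for uniform turning.
- **Missing-arc correction.** A detected circle typically closes between
  350° and 370°, leaving a small uncancelled arc of air velocity whose
  direction is set by the anchor phase — and anchors are phase-aligned
  within a cluster, so the bias (≈ TAS·Δθ/2π, several tenths of m/s) does
  not average out. The estimator therefore solves
  wind = mean(v) − TAS · (mean unit air-velocity) by fixed-point iteration
  (8 iterations, geometric convergence for W < TAS), which removes the
  bias; for an exactly closed circle it reduces to the plain vector mean.

TAS is the duration-weighted mean of |ground velocity − wind| after chord
correction. Two scalar diagnostics of the ground-speed trace are reported
for comparison with the classical read-the-sine-wave analysis:
`sinusoid_mean` (time-weighted mean ground speed, → TAS for W ≪ TAS) and
`sinusoid_amplitude` (half of max − min, → W). For wind weaker than the
airspeed the amplitude tracks the *wind* and the mean tracks the *airspeed*
— the vector-sum geometry forces this assignment, and the estimator follows
it; both diagnostics are emitted so either reading can be inspected.
Estimation requires ≥ 350° of accumulated turn and raises a contract error
otherwise.

The estimator degrades as W/TAS → 1: the ground heading develops near-cusps
and heading-return circle detection fails before the estimator does
(empirically, label recovery collapses near W/TAS ≈ 0.95). The default
synthetic scenario keeps W/TAS ≤ ~0.85 at circling altitudes for this
reason; a real flight circling in wind equal to its airspeed would need a
position-loop (not heading-loop) circle detector, which is out of scope.

**Sink accounting.** The wings-level best-glide sink rate defaults to
−0.75 m/s (a conservative figure for a large eagle; published vulture
values run −0.9 to −1.9 m/s). Banking at angle β reduces the vertical lift
component by cos β, so circling sink is base/cos β (−0.83 m/s at the
assumed 25° bank, a ~10% increase). The glide up/down threshold uses the
wings-level value; circling analyses use the banked value. Ambient vertical
air motion is observed climb minus still-air sink (w = c − s); bulk wind
shear is Δspeed/Δheight between two levels.

## Energy–distance budget

Circling is assumed to contribute no airspeed-driven progress toward the
migration target; during circling time T_c the bird drifts downwind, giving
D_c = tailwind × T_c. During glide-down time T_g it advances at the mean
glide ground speed: D_g = GS_glide × T_g. The leg is feasible without
flapping when D_t = D_c + D_g ≥ the direct distance. "Conserving metabolic
energy" is operationalized exactly as distance sufficiency under the
no-flapping assumption — no metabolic-power model is attempted. The
companion L/D check reports the still-air glide range |height loss| × L/D
(L/D = 15 for large birds) and the ratio of achieved glide distance to it;
tailwind-assisted ratios above 1 are expected and flagged as such, not
errors.

Budget inputs come in two modes, with provenance recorded: explicit
printed constants, or quantities recomputed from a classification. In the
fitted-model route, T_c is the total span of the circling sequences (first
circle entry to last circle exit, plus isolated circles outside sequences)
— the quantity such analyses print, which also credits tailwind drift
through the partial turns between closed circles — and the tailwind is the
duration-weighted mean wind vector over circles in the **upper quarter** of
the circling-altitude range, projected once onto the migration course.
Using the flight-level wind rather than a whole-climb average mirrors how
such budgets quote a single tailwind at the established migration altitude;
both choices are logged in the output's provenance fields. Distances are
reported in km to one decimal; internal math is meters and seconds.

## Synthetic soaring flight

The generator exists to provide ground-truth-labeled tracks that
statistically resemble a ~2 h, ~100 km wave-soaring migration leg: ~22 s
circles in clusters of ≥ 3, climb rates of 1–3 m/s, inter-cluster
descending glides at ~15–23 m/s ground speed, altitude oscillating between
a 600 m AGL working floor and a 2000 m AGL ceiling, horizontal wind
strengthening from 4.5 to 11.5 m/s and veering with height, and GPS noise
at the receiver's published accuracy.

**Wave field.** Vertical air velocity is a sum of stationary monochromatic
wave layers, each
w = A · sin(2π d/λ + φ) · exp(−(z − z₀)²/2σ_z²), where d is the horizontal
projection onto the wave-normal azimuth. The default scenario sums three
layers sharing the 20° normal and φ = 0: a main elevated wave
(A = 3.2 m/s, λ = 10 km, z₀ = 2000 m ASL, σ_z = 400 m), a low-level
terrain-induced wave (A = 3.0, z₀ = 1100, σ_z = 350) that keeps lift
reachable below the main layer and supports climb-out from the floor, and a
weaker short secondary wave (A = 1.5, λ = 4.5 km, z₀ = 1600, σ_z = 600)
riding on the train, which strengthens some crests and moderates some
troughs so climb/glide cycles occur more often than the dominant
wavelength alone would give. The amplitudes follow from an energy balance:
the bird drifts through the rising half-wavelength at wind speed (~8 m/s)
but crosses the sinking half at glide ground speed (~20 m/s), so a
self-sustaining sawtooth needs crest lift to exceed sink by roughly that
speed ratio — combined crest amplitude ≈ 3.3 m/s, putting peak climbs
(A − 0.83) inside the observed 1–3 m/s. Phase 0 starts the flight entering
a rising half-wave so the first climb can harvest the full lift band. A
single `WaveField` keeps a simple default (A = 2 m/s) for direct use.

**Flight policy.** A discrete-time agent (Δt = 1 s) with three modes.
GLIDE holds a per-leg heading drawn within ±45° of the migration heading
(route-scale wandering that, as in real tracks, makes the flown path ~20%
longer than the direct line) and sinks at w + base_sink. CLIMB circles at
360°/22 s with vertical rate w + base_sink/cos 25°; direction is drawn per
cluster and reverses between consecutive circles with probability 0.12;
reversals and glide exits are committed at circle closure but applied after
a 30° roll-out arc, as a banked bird reversing or leveling would fly.
MEANDER (entered below the 600 m AGL floor without lift) is a run-and-
tumble search: gently curving runs (1.5–4°/s bias) while the encountered
lift improves, sharp reorientation when it worsens. Transitions use lift
hysteresis: a gliding bird starts circling only after 5 s of banked climb
rate ≥ 0.9 m/s (strong cores → fast climbs and a glide-heavy time budget),
keeps circling until it falls below 0.2 m/s or hits the ceiling, and a
searching bird takes any positive lift. Horizontal motion integrates air
velocity plus the height-interpolated wind; positions convert to geodetic
coordinates about 38.8° N, 79.0° W by local flat-earth mapping (curvature
error negligible over ~125 km for testing purposes). Per-step altitude
bookkeeping is exact: Δalt = (w + mode sink)·Δt, asserted in tests. All
randomness flows through one seed; identical seeds give bit-identical
tracks.

**GPS noise.** Independent zero-mean Gaussian perturbations per fix,
σ_h = 1.0 m horizontal and σ_v = 11.0 m vertical, interpreting the
receiver's published "<2 m horizontal, <22.5 m vertical" accuracies as
~2σ bounds. Labels and truth fields are untouched.

**What the simulator does and does not emulate.** It reproduces the
*statistical signature* of wave soaring — cluster spacing, circle
durations, climb rates, glide speeds, the altitude sawtooth, wind veer, and
the feasibility of the leg (D_t ≥ direct on the default scenario) — and so
validates the classifier, the wind estimator, and the budget pipeline
end-to-end. It does not emulate a numerical weather model's flow field,
terrain-resolved dynamics, thermals, turbulence, wave asymmetry, or the
behavioral richness of a real bird; its troughs are deeper than the gentle
~−1 m/s mean glide sink seen in the real flight, so its bird circles a
larger share of the time than the real one did. Passing closed-loop tests
therefore demonstrates correctness of the analysis chain on wave-like
motion, not fidelity of any particular atmospheric simulation.

## Verification strategy and problem sizes

The suite (≈ 140 tests, seconds of runtime) combines exact oracles
(closed-form circle geometry, dense numeric integration of ground-speed
traces, budget arithmetic), property-based tests (hypothesis: budget
identities, scale equivariance, triangle inequality, estimator exactness
over random airspeed/wind), and closed-loop recovery on the default
scenario: ≥ 95% of fixes receive their generating label without noise and
≥ 85% with default noise; cluster-averaged wind recovery within 0.2 m/s
per component; partition and altitude-conservation invariants; and
end-to-end budget feasibility. Simulated flights are 7600 s at 1 Hz — the
full study-scale problem — since the whole pipeline runs in under a second
per flight.

## Known limitations

- Heading-based circle detection fails as W/TAS → 1 (see above); the real
  low-altitude circles of such flights, flown in wind comparable to the
  airspeed, would need position-loop detection.
- The glide up/down split labels whole straight runs by their mean climb
  rate; a long glide crossing lift and sink in one straight line is a
  single segment.
- Meander has no positive definition; it is the moving, heading-variable
  residue, so its statistics depend on the other two classifiers.
- The wind estimator assumes constant airspeed and constant wind within a
  circle; height-varying wind within a single 22 s circle biases the
  estimate by the within-circle wind change (small at ~1 m/s per 100 m of
  climb).
- Terrain lookup is bilinear (nearest-neighbor optional) on a regular
  lat/lon grid; no reprojection of projected-CRS rasters.
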