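# Methods

`fessmotion` turns raw wrist-worn accelerometer recordings from endoscopic
sinus surgery training into three *economy-of-motion* metrics — procedural
time, resultant acceleration, and path length — and compares them across
surgeon experience groups (resident / specialist / senior) with a
nonparametric battery. Because no raw recordings from such studies are
publicly deposited, the package ships a ground-truthed simulator whose
cohort-level set points are the published group means; every stage of the
pipeline is validated by recovering what the simulator was told to produce.

## Signal model and preprocessing

An accelerometer measures specific force: linear acceleration minus gravity,
expressed in the sensor frame — at rest it reads +1 g. Ingested recordings
(CSV, column-mapping configurable, acceleration declared in g or m/s²;
silent unit guessing is forbidden because a 9.8× error would corrupt every
metric) are normalised to m/s² on a strictly increasing time base, nominally
128 Hz. Jittered exports are linearly resampled onto a uniform grid.

Gravity removal offers three routes, selected automatically by default:

* **orientation** — rotate nominal gravity by the per-sample roll/pitch and
  subtract; exact whenever an orientation stream is present (preferred).
* **static_subtract** — subtract the mean specific force of a detected (or
  declared) still window, the analogue of a neutral-pose calibration; exact
  only while the wrist does not rotate, so a window whose |a| std exceeds
  0.5 m/s² flags calibration failure and falls back to
* **highpass** — zero-phase high-pass per axis at 0.25 Hz (below the
  voluntary-movement band, above drift).

All filters are zero-phase forward–backward Butterworth (order 4) so time
metrics are never phase-shifted; a 20 Hz low-pass strips wide-band sensor
noise while passing hand motion and physiological tremor.

## Metrics

* **Procedural time** `t_last − t_first` (s).
* **Resultant acceleration** `|a_i| = sqrt(ax² + ay² + az²)` per sample of
  the gravity-free, smoothed signal (a config switch uses raw specific force
  instead). Both the per-sample mean and the per-sample **sum** over the
  trial are reported. The published group tables carry values in the
  thousands of m/s², which are physically impossible as mean instantaneous
  accelerations at surgical-hand scales; the cumulative (per-sample summed)
  reading is the only interpretation consistent with those magnitudes, so
  the cumulative quantity is treated as the table-level metric while the
  mean is reported alongside. This interpretation is an assumption, stated
  here rather than hidden.
* **Path length** is computed in velocity space, `Σ |v_i| Δt`, never from
  doubly integrated positions, to keep noise drift linear rather than
  quadratic; positions are integrated once more only for the start-to-end
  displacement diagnostic (and `path ≥ displacement` always holds, a
  triangle-inequality property the tests enforce on arbitrary inputs).

### Drift correction (ZUPT)

Velocity comes from trapezoidal integration of the gravity-free signal and
is drift-corrected by zero-velocity updates: surgical hand motion contains
micro-pauses, and velocity there is pinned to zero with the accumulated
drift interpolated between pauses. The detector had to be made robust to two
features of very gentle motion that defeat the textbook
"|a| < threshold for ≥ 150 ms" rule:

1. **Candidate stills** are runs where the per-axis 5 Hz low-passed
   acceleration norm stays under `min(0.3 m/s², 0.6 × P90(|a|))`. The
   low-pass sits below the 8–12 Hz tremor band (applied per axis before the
   norm — rectified tremor has a DC component no low-pass of the magnitude
   itself can remove), and the adaptive cap keeps traces whose peak |a| is
   below the absolute threshold (slow multi-second reaches peak near
   0.25 m/s²) from being declared still wholesale.
2. **Vetting**: |a| also dips through any threshold mid-reach, at the
   acceleration zero-crossing — exactly where speed peaks, the worst place
   to pin velocity to zero. At a genuine still the raw integrated velocity
   equals the accumulated drift, a slowly varying trend shared with
   neighbouring stills; a mid-reach dip sits a full movement speed off that
   trend. Candidates whose (median) velocity deviates from the local
   sample-weighted median of all candidates by more than
   `max(0.05 m/s, 3 × lower-quartile residual)` are discarded; the lower
   quartile estimates genuine-still scatter even when false dips make up
   half the candidates.
3. **Anchoring**: one drift anchor per surviving run, at the run centre
   (velocity is exactly zero mid-pause). Anchoring on run edges, where
   velocity still carries a few cm/s in the movement direction, was measured
   to bias path length down by ~10% on analytic-truth traces; centre
   anchoring removes that bias (noise-free recovery error ≈ −0.5%, from the
   deliberately pinned low-speed dwell around each pause).

When no still interval survives, a zero-phase 0.25 Hz high-pass on velocity
is the fallback; `drift_method: none` is available for diagnostics.

## Synthetic cohort generator

A trial is a chain of `n` straight minimum-jerk submovements (the standard
model of skilled reaching; position profile `10τ̂³ − 15τ̂⁴ + 6τ̂⁵`, so
acceleration has the closed form `(D/τ²)(60τ̂ − 180τ̂² + 120τ̂³)`) between
random waypoints, separated by 80–200 ms micro-pauses plus 0.6 s of still
padding at each end (ZUPT anchors and calibration window). Each min-jerk
segment of amplitude `D` and duration `τ` contributes exactly `3.75 D/τ` to
`∫|a| dt`, so for equal segments the three cell targets — duration `T`, path
`L`, cumulative acceleration `C` at rate `f` — pin the structure:

    C = f · 3.75 · L · n / T_move   ⟹   n = C · T_move / (3.75 · f · L).

The solver rounds `n`, re-solves the movement time so the identity is exact,
and assigns the remainder of `T` to pauses; a final scalar rescale of the
sampled noise-free acceleration makes the *discrete* cumulative resultant
hit the target exactly (the analytic truth records the post-rescale values,
so truth and signal never disagree). Targets implying peak hand speeds above
5 m/s are refused as infeasible. Skill differences enter *only* through the
per-cell targets and the derived segment structure — there is no separate
skill-noise channel the statistics could latch onto.

On top of the noise-free trajectory the sensor model adds, per axis: gravity
along a slowly wobbling orientation (±15° amplitude, 0.02–0.08 Hz; angles
and angular rates are exported so orientation-based removal is testable),
one band-limited tremor sinusoid (8–12 Hz, 0.15 m/s² default), and white
noise (0.05 m/s² default). The wobble tilts gravity while the linear
acceleration stays in a fixed frame — a deliberate simplification (no
`ω × v` coupling) that keeps the exported orientation an exact key for
gravity removal and the analytic truth exact.

### What the set points force, and what that implies

The published cell means put the simulator in an unusual regime worth
stating plainly:

* Paths of 30–65 m per few-minute task with cumulative accelerations of only
  3 000–10 000 m/s² (summed at 128 Hz) solve to submovements of up to 3.5 m
  at under 1.5 m/s — implausibly large for a wrist but the only straight-
  segment structure satisfying all three targets at once. The waypoint walk
  therefore uses a soft attraction toward the origin rather than a hard
  workspace box. (Such path magnitudes are themselves a signature of
  uncorrected integration drift in the original measurements; this package
  does not attempt to reproduce that bias, it reproduces the printed values
  as generator targets.)
* Reproducing the published universal significance (Kruskal-Wallis
  p < 0.001 in *every* procedure × hand cell for all three metrics, with
  per-recording observations and group sizes 10/10/4) requires
  near-complete rank separation of all three groups: the chi-squared bound
  needs H > 13.8 of a maximum 19.6. The closest pair of published cell
  means differs by 1.1% (dominant-hand ethmoidectomy path, 55.7 vs 56.3 m),
  so the between-participant coefficient of variation must stay below
  roughly a quarter of that gap. The shipped default cohort therefore uses
  `between_subject_cv = 0.0025`, and draws each group's skill multipliers
  variance-matched (re-standardised to mean exactly 1, SD exactly the CV),
  so realized cell means sit on the set points and the expertise ordering
  holds by construction. A realistic surgical cohort would show CVs an
  order of magnitude larger — and with, say, `between_subject_cv: 0.10`
  (the single-trace profile default) the closest cells are statistically
  indistinguishable at n = 24. That tension is a property of the published
  summary numbers under per-participant testing, not of this
  implementation; the CV is a single YAML field for anyone who wants to
  explore it.

### What the simulator does *not* emulate

Real recordings contain wrist-rotation-coupled accelerations, non-stationary
tremor, sensor bias walk, Bluetooth dropouts and genuinely idiosyncratic
movement strategies. Passing recovery tests on this generator demonstrates
that the pipeline is internally consistent and unbiased under its stated
signal model — not that it would recover truth on real hands, where gravity
leakage through imperfect orientation estimates is the dominant error.

## Statistics

The unit of observation is one recording's metric value (one per
participant × hand × procedure: group sizes 10/10/4 per cell — the
statistically defensible reading of a per-participant design). Per cell:
group mean and sample SD (n−1), per-group Shapiro-Wilk, and a tie-corrected
Kruskal-Wallis H referred to chi-squared with k−1 df (the behaviour of
standard statistical software even at n_min = 4; a seeded Monte-Carlo
permutation p is available behind a config flag, and a type-I-error
simulation in the tests confirms the chi-squared approximation holds its
level at these group sizes). No multiple-testing correction is applied,
matching the study design; the report states the number of tests performed.
Dunn pairwise comparisons are implemented but off by default. Degenerate
cells (constant data, too-small groups) are flagged in the output, never
fatal.

## Problem sizes and determinism

The default cohort is 24 participants × 5 procedures × 2 hands =
240 recordings (0.7–7.5 minutes each at 128 Hz, ≈ 8 M samples total);
simulation plus metrics plus the battery runs in well under a minute on one
core. Acceptance-style recovery checks use 10 seeded low-noise traces per
cell (`sensor_noise_sd 0.01, tremor 0.02, cv 0`). Cohort generation is a
pure function of (spec, master seed); trace seeds derive from a seed
sequence, and reports embed the configuration hash that produced them.

## Known limitations

* The cumulative-acceleration reading of the published tables is an
  interpretation; if the original quantity was something else (e.g. device
  counts), only the generator set points — not the pipeline — would change.
* ZUPT vetting assumes drift varies slowly relative to the ~15 s trend
  window; aggressive sensor bias walk would need the window shortened.
* Timing is derived from the recording span, which assumes the operator
  starts/stops the recording with the task.
* The orientation route trusts the exported angles; real sensor fusion error
  propagates directly into the gravity residual. Full attitude estimation
  (Kalman/Madgwick) is out of scope.
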