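# Methods

## Scope and model

`wormcycle` quantifies *C. elegans* undulatory locomotion and body-wall
muscle calcium activity cycle by cycle. The animal bends dorsoventrally
with an approximately periodic rhythm; the package's unit of analysis is
the **undulation cycle**, the interval between two successive dorsal-bend
maxima of a reference body point. All phase-resolved quantities are
expressed in **cycle fraction** φ ∈ [0, 1) with φ = 0 at the dorsal-bend
maximum. Consequently, under the swimming co-activation regime, straight
postures — where both dorsal and ventral muscles peak — fall at φ = 0.25
and φ = 0.75.

Sign convention, package-wide: **positive bend = dorsal**. In synthetic
data the lab frame is oriented with dorsal toward +y; users of real tracks
must orient their coordinates accordingly.

## Synthetic-data generator

The generator exists so that every analysis stage has a recoverable ground
truth. It is first-class, tested code, not a fixture.

### Bend wave

The reference-point phase is φ(t) = (t/T) mod 1. The bend is a
unit-amplitude *warped* sinusoid Ψ built from two time-rescaled cosine
half-periods: the dorso-ventral (descending) sweep occupies fraction
1 − f_D of the period and the ventro-dorsal (ascending) sweep occupies
f_D. Its positive lobe is scaled by the dorsal amplitude gain a_d, the
negative lobe by the ventral gain a_v, so the bend at body position s is

    θ(s, t) = A · Ψ(φ(t) − (s − s_ref)/λ)

with A the peak bend (degrees), λ the wavelength in body lengths, and
s_ref the reference body fraction. Because each half is a rescaled cosine,
half-cycle slopes scale analytically as 1/(1 − f_D) and 1/f_D, and the
angular excursion is A·(a_d + a_v).

### Postural model

The geometric midline is a **two-arm articulated model**: a straight
anterior body axis and a straight tail arm joined at the tail-gap body
fraction (`hinge_s`, default 0.8), with hinge angle equal to the warped
wave at the reference point. The anterior arm takes a share `anterior_weight`
(default 0.5) of the hinge angle and the tail arm the remainder, so both
head and tail sweep. Points are spaced at equal arc length (exactly
constant total length) and the chain is anchored at its centroid before
translation is applied.

This articulated geometry was chosen over a distributed traveling-wave
tangent profile deliberately: the tail-angle assay measures the
three-point chord angle (tip, vertex, anterior point), and with straight
arms that measurement recovers the generated bend *exactly*, making
amplitude-recovery and excursion tests sharp instead of
attenuation-dependent. The traveling wave still governs per-muscle
activation (below), which is what the calcium pipeline consumes. The cost
is that the rendered worm is a two-segment polyline rather than a sinuous
body — adequate for ROI-readout tests, not for testing posture trackers.

### Propulsion

Forward translation uses a stroke-dependent thrust model: instantaneous
speed is `translation_speed` weighted by 2a_v/(a_d + a_v) during the
dorso-ventral sweep and 2a_d/(a_d + a_v) during the ventro-dorsal sweep.
Rationale: the muscle group driving a sweep contributes force in
proportion to its amplitude gain. For a strictly periodic posture with no
translation, the head positions at consecutive dorsal maxima coincide and
the two per-sweep head displacements are *identical by periodicity*;
asymmetric per-sweep thrust is the mechanism by which ventral-dorsal
amplitude asymmetry manifests as the d_V > d_D displacement asymmetry seen
in real swimming. With a_d = a_v the model reduces to uniform translation.

### Emission models

With κ_m(t) the local bend signed positive toward muscle m's own side and
κ̂ its per-trace maximum magnitude:

- crawl (antiphasic): F_m = B + g_m·max(0, κ_m)/κ̂ + ε — each muscle peaks
  at its own bend extremum, silent during the opposite sweep;
- swim (co-active): F_m = B + g_m·(1 − |κ_m|/κ̂) + ε — both sides peak at
  straight posture, silent at the bend extremes.

ε is i.i.d. Gaussian with sd σ; optional photobleaching multiplies the
noise-free signal by exp(−t/τ). The background trace is F_bg0 + ε. Shot
noise (intensity-dependent variance) is deliberately not modelled; at the
σ/g ratios used it would not change which tests pass, but conclusions
about real shot-noise-limited recordings should not lean on this
generator.

### Anatomy

Four longitudinal quadrants; ventral-left has 23 myocytes and
ventral-right 24 (fixed asymmetric anatomy), dorsal quadrants default to
24 and are overridable. Cell k of an n-cell quadrant sits at body fraction
(k − ½)/n. Generic names resolve leftward with rightward fallback:
``vm21`` → VL21; ``vm24`` → VR24, the most posterior ventral cell, because
VL has no 24th cell. ``vm21`` lies just posterior to the spermatheca;
``dm21``/``dm24`` are its dorsal counterparts.

### Defaults (the simulated study conditions)

| parameter | default | note |
|---|---|---|
| fps | 10 | frame rate of the emulated recordings |
| duration | 17 s | single-recording length |
| period T | 2 s | swim cycle duration |
| amplitude A | 45° | peak bend before lobe scaling |
| wavelength λ | 1.5 BL | body-wave wavelength |
| f_D | 0.5 | ventro-dorsal sweep fraction |
| baseline B | 100 a.u. | emission floor |
| gain g | 100 a.u. | per-muscle emission gain |
| background F_bg0 | 50 a.u. | background region level |
| noise σ | 10 a.u. | σ/g = 0.1, the recovery-test regime |
| body length | 1000 µm | adult hermaphrodite scale |
| translation speed | 150 µm/s | slow-swim centroid speed |

Per-animal sub-seeds derive from the master seed through a counter-based
`SeedSequence([master, ordinal])`, so cohorts are bitwise reproducible and
animals are statistically independent.

## Kinematics

- **Bend angle**: 180° minus the interior angle at a chosen vertex,
  computed from three midline points, signed by which side the tip falls
  on. Collinear points give 0.
- **Cycle detection**: 3-frame moving-average smoothing (default), then
  local maxima with prominence ≥ 0.2 × trace range and spacing ≥ 0.3 s
  (defaults chosen to be robust at 10 fps; all configurable). Cycles are
  half-open frame intervals between consecutive interior maxima; a cycle
  must contain an interior minimum (the ventral bend). The first and last
  samples are never boundaries, so a recording of n nominal periods yields
  n − 1 complete cycles.
- **Half-cycle slopes**: least-squares line fit over each half (opening
  maximum → minimum, and minimum → closing maximum), endpoints included,
  reported as magnitudes in deg/s. A least-squares fit rather than a
  two-point secant was chosen for noise robustness; the two agree exactly
  on linear ramps.
- **Lateral displacement**: Euclidean head-tip displacement over each
  sweep (head tip = first midline point; a head-region centroid is the
  plausible alternative and would differ only by a smooth spatial
  average).
- **Centroid speed**: total centroid path length / elapsed time.
- **Path curvature**: the trajectory is resampled at uniform arc-length
  steps (default 50 µm ≈ body length / 20) and the summed unsigned
  turning angle is divided by the path length (rad/µm). The resampling
  grid uses ⌊L/step⌋ equal steps spanning the whole path, which makes the
  estimate exactly invariant to traversal reversal and rigid motions. The
  estimator carries an O(1/N) edge bias on open smooth paths (N resampled
  steps), relevant when validating against constant-curvature identities.

## Calcium

- **Background normalization**: ratio F_roi/F_bg by default; ΔF/F is a
  config switch (`mode="dff"`). The ratio convention is the package
  default because both conventions yield identical *ratios between
  muscles* when the background is shared, which is what the asymmetry
  metrics consume.
- **Time normalization**: K = frame count of the longest cycle in the
  recording (per recording, not per cohort); each cycle is linearly
  interpolated at fractions k/K of its own span. Cycles already of length
  K are reproduced exactly.
- **Half-cycle means**: columns φ < 0.5 and φ ≥ 0.5, averaged within a
  cycle first and then unweighted across cycles. With f_D = 0.5 the first
  half is the dorso-ventral sweep.
- **AUC**: trapezoidal integral over φ ∈ [0, 1] per cycle, closing the
  period by wrapping the first grid value to φ = 1, averaged across
  cycles. Computed on the normalized trace without baseline subtraction
  (relative activation); subtract externally if absolute transients are
  wanted.
- **Peak phase**: local maxima of the across-cycle mean profile; the
  wrapped boundary is checked so a peak at the dorsal-maximum origin is
  reported as φ = 0. Resolution is one grid step (1/K).
- **Activation ratio**: whole-cycle-mean mode recovers emission-gain
  ratios exactly on noise-free zero-baseline input; contraction-peak mode
  (default) samples the mean profiles at the dorsal- and ventral-peak
  fractions (0 and 1 − f_D by default) and averages the two, matching the
  at-the-peaks comparison convention.

Phase-locking caveat: a muscle's activation is phase-locked to *its own*
segment's bending. If the cycle reference vertex sits at a different body
fraction than the quantified muscle, the wave travel delay (Δs/λ) shifts
every phase metric by up to one grid step. Analyses that quote peak
fractions therefore colocate the reference vertex with the muscle of
interest (as the worked example and the acceptance script do).

## Statistics

Per-group Tukey-fence outlier removal (linear-interpolation quartiles,
1.5 × IQR, no removal below n = 4, applied before the normality gates),
then Shapiro-Wilk normality and Brown-Forsythe (median-centered Levene)
equal-variance gates, both at α = 0.05. Dispatch: Student t / Welch t /
Mann-Whitney for two groups (paired t / Wilcoxon signed-rank on
differences when paired); one-way ANOVA with Holm-Sidak pairwise post hocs
(pooled error term) or Kruskal-Wallis with Dunn's tie-corrected rank
post hocs (Holm-Sidak adjusted) for three or more. The recorded normality
and variance verdicts are exactly the component tests run in isolation on
the outlier-cleaned samples.

Single-pass outlier semantics: iterated Tukey fencing can cascade
(removing a point shrinks the IQR and can expose new "outliers"), so the
rule is applied exactly once per group.

Power (1 − β) is estimated by Monte-Carlo for *every* branch, parametric
ones included: datasets are simulated under a normal shift alternative at
the stated effect size, the chosen test is re-run, and power is the
rejection fraction with binomial SE. For the Student-t branch this
converges to the analytic noncentral-t power, which the test suite uses as
an independent oracle; for rank-based branches no closed form exists and
the simulation is the estimate. The common-random-numbers trick (same
seed per grid point) is used when scanning effect sizes to keep power
curves monotone at modest replication counts.

## What the synthetic tests do and do not show

Passing the suite demonstrates that the *measurement pipeline* is correct:
cycle segmentation matches brute-force peak scans, time normalization
matches hand interpolation, phase metrics recover the emission models'
analytic peak structure, and gain asymmetries injected into the generator
are recovered through the full pipeline at realistic noise. It does not
validate worm tracking or segmentation from raw video (out of scope), nor
does it certify behavior on real recordings with non-Gaussian noise,
tracking dropouts, irregular rhythms, or behavioral state switches — none
of which the generator emulates.

## Problem sizes

Test and acceptance runs use single recordings of 17–44 s at 10 fps
(170–440 frames), cohorts of 10 animals per condition, 100 replicate
cohorts for the detection-rate check, and 10 000 Monte-Carlo replicates
for power calibration. These sizes give sub-percent Monte-Carlo error on
every asserted quantity while keeping the whole suite fast on one CPU.
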