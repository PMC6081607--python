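# Methods

## The task and its two scoring arms

A visual paired comparison (VPC) trial presents one familiar and one novel
image side by side for 5 s after a 2 s or 2 min delay. The memory signal is
novelty preference (NP): the fraction of on-stimulus viewing spent on the
novel image. A subject's overall score is the unweighted mean NP over the
retained, defined test trials (20 by default).

Two measurement channels estimate the same quantity:

* **Duration scoring (60 Hz).** Each gaze sample carries per-eye normalized
  screen coordinates (origin top-left, unit square) and a validity flag.
  The definitive gaze estimate is the binocular midpoint, falling back to
  the single available eye. Fixations are found with a dispersion-based
  (I-DT) filter: maximal runs of usable samples whose bounding-box diagonal
  stays within a threshold and which span a minimum duration. Each
  fixation contributes (number of samples × sample period) of viewing time
  to the AOI containing its centroid; NP is the novel share of on-AOI
  fixation time. A trial is automatically excluded when strictly more than
  4 s of samples are invalid (4000 ms exactly is retained, matching the
  "more than 4 s" reading of the rule); the missing clock counts test-phase
  samples only. Aberrant gaze patterns (a single cluster holding >95% of
  fixation time, off-AOI-dominant viewing, outlying saccade counts) raise
  advisory flags but never exclude on their own — in practice that decision
  belongs to human reviewers.

* **Frame scoring (3 FPS).** The stream is down-sampled by keeping every
  (sample rate / frame rate)-th sample as an instantaneous frame (no window
  averaging — a video frame is an instant). Three independent raters label
  each frame left / right / neither; the per-frame majority vote wins, and
  any tie for first place abstains to *neither* since a tied frame carries
  no directional evidence. Trial NP is novel-side frames over
  (novel + familiar) frames, *neither* frames excluded from both numerator
  and denominator. No automatic trial-exclusion rule applies to this arm by
  default; an optional neither-count limit is available but off.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `dispersion_threshold` | 0.05 (normalized units) | I-DT bounding-box diagonal limit; standard I-DT range for screen-normalized data |
| `min_duration_ms` | 100 ms | minimum fixation span |
| AOI boxes | centered 40%-width rectangles in each screen half | stimulus extents |
| `margin` | 0.10 | fractional AOI expansion per side ("slightly larger" than the image) |
| missing-data limit | 4000 ms | automatic exclusion threshold, strict inequality |
| `sample_hz` / `frame_fps` | 60 / 3 | the two arms' rates; must divide evenly |
| `n_raters` | 3 (odd required) | majority vote well-defined |

The fixation-filter constants and AOI geometry are declared conventions:
the upstream hardware pipelines this package models do not publish theirs.
All defaults are configurable and all reliability figures in this package
are computed at the declared defaults.

## The synthetic cohort generator

The generator exists so that every pipeline stage can be validated against
known truth. Its latent structure:

1. ability ~ N(0, 1) per subject;
2. subject mean NP = monotone quantile map of ability into the configured
   distribution (default Uniform(0.45, 0.90) — a spread wide enough to
   cover impaired-to-strong novelty preference without asserting a
   population shape);
3. trial true NP = subject mean + N(0, 0.08), clipped to [0, 1];
4. novel side balanced across trials; the 2 s / 2 min delay condition is
   recorded as metadata but does not alter generation by default (no
   condition-specific effect is assumed);
5. each cognition component z = coupling·ability + √(1−coupling²)·noise,
   rescaled to a synthetic normative table (plausible means/SDs for
   clinically normal older adults; reverse-scored timed measures flip
   sign on the raw scale), so every component's population correlation
   with ability is exactly the coupling (default 0.4).

A trial's gaze stream realizes its true NP *constructively* rather than
statistically: the 5 s trial is laid out as dwell segments on the novel and
familiar AOI joined by a 4-sample saccade whose travel positions stay
strictly between the expanded AOIs. On-AOI sample counts are allocated so
the novel share equals true NP to within one sample, and the single side
switch sits inside one 3 FPS frame block, so the frame-sampled NP can
disagree with true NP by at most one frame's weight. This makes the
generator-honesty property — duration NP ≈ frame NP ≈ true NP with all
noise silenced — an exact guarantee the tests check per trial, not an
asymptotic claim.

Noise sources, each independently configurable and each defaulting to a
plausible magnitude: rater error (3% per rater per frame, modeled as a
left↔right direction flip; blink frames stay *neither* — a "uniform"
confusion mode is available), blinks (5% of frame instants, stamped into
the gaze stream as short invalid runs so both arms see the same event), and
tracker dropouts (0.5 runs per trial of 100–500 ms). Within a dwell
segment, gaze is a chain of 300–900 ms fixations with 0.004-SD jitter, and
the two eyes sit ±0.012 either side of the intended midpoint so the
binocular midpoint reproduces it exactly.

What the generator does **not** emulate: smooth pursuit, drift and
microsaccade dynamics, head movement, calibration decay over the session,
asymmetric or correlated rater errors, condition effects of the delay
manipulation, and any dependence of data quality on ability. Passing tests
therefore demonstrate that the *scoring and statistics* are faithful, not
that real webcam data of this quality is guaranteed.

## Calibration

The calibration dot pauses ~2 s at nine known points — (0.5, 0.5),
(0.1, 0.1), (0.1, 0.9), (0.9, 0.9), (0.5, 0.5), (0.9, 0.1), (0.5, 0.1),
(0.1, 0.5), (0.5, 0.9). Coder validation scores dwell frames only (not the
travel between points) against the 3×3 grid cell containing the dot; a
coder below 90% must recode. The grid granularity is a declared convention:
the original coders judged direction, and a 3×3 grid is the coarsest
partition that distinguishes all nine waypoints. The per-subject gaze
model is a 6-parameter affine least-squares map from raw gaze to screen
coordinates — the simplest individualized model that is exactly testable
(it inverts any noise-free affine distortion of the path to < 1e-9
residual); degenerate (collinear) calibration clusters are rejected.

## Statistics

* **Agreement** is Krippendorff's coefficient for nominal data via the
  coincidence matrix, with per-unit pairable counts handling missing codes.
  The applied literature this package follows sometimes calls the quantity
  "Krippendorff's kappa"; the output carries that alias. With every code
  identical the coefficient is defined as 1.
* **Spearman's rho** uses mid-ranks (tie-corrected Pearson on ranks). The
  two-tailed p is exact by permutation enumeration for n ≤ 7 and the usual
  t-approximation otherwise.
* **Comparing correlations**: the independent-samples Fisher r-to-z test is
  the pipeline default; a dependent (overlapping, Steiger/Meng-style) test
  is available when the correlation between the two measures is supplied.
  Degenerate inputs (|r| = 1, n ≤ 3) are rejected rather than silently
  transformed.
* **Strength bands**: |r| ≥ .50 strong / .30 moderate / .10 weak for
  correlations; ≥ .80 strong / .60 moderate / .40 weak for agreement.
  Boundary values belong to the band whose printed range includes them.

The NIHTB composite here is a z-mean surrogate: the battery's own summary
is an IRT theta score whose item model is internal to the battery, so the
package documents its composite as a stand-in with the same components
(Flanker, PCPST, DCCS, PSMT) rather than imitating the theta estimation.

## Numerical choices

* Missing time is (invalid samples × 1000 / rate), multiplied before
  dividing so that 240 invalid samples at 60 Hz compare exactly equal to
  4000 ms.
* The fixation minimum-duration comparison carries a 1e-6 ms tolerance:
  timestamps built from a rational sample period (1000/60 ms) otherwise
  miss exact-length runs by float error.
* Fixations straddling an AOI boundary are assigned by centroid —
  deterministic and order-free.
* Subject-level means are unweighted over retained, defined trials; a
  subject with no retained trials has undefined NP and drops out of
  correlations pairwise.

## Reliability studies and problem sizes

The acceptance script and test suite measure three coefficients on
simulated data at the assessment's own design size — 44 subjects × 20
trials × 15 frames, 3 raters at 3% flip error: the inter-rater agreement
coefficient, and subject- and trial-level cross-camera correlations. The
parameter-recovery study uses 500 subjects × 10 seeds with coupling 0.4 and
checks the frame-arm NP–PACC Spearman against its closed-form
generator-implied value, (6/π)·asin(r/2) with
r = c/√(c² + (1−c²)/4), within 3 standard errors on the Fisher-z scale.
These sizes keep each study well under a couple of minutes on one core
while leaving Monte-Carlo error far smaller than the margins being tested.

## Known limitations

* The I-DT filter is a stand-in for the unpublished cluster-based filter
  used with the original 60 Hz hardware; equivalence with that filter
  cannot be established from public information.
* Frame-coded validity depends on human coders the package only simulates;
  the rater error model (independent symmetric flips) is optimistic about
  systematic coder bias.
* The delay-condition split across the 20 trials is exposed as a parameter
  with a 50/50 default and no claim of fidelity to any particular protocol.
* Normative values shipped with the generator are synthetic; real analyses
  must supply their own `norms.yaml`.
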