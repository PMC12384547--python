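# Methods

## The problem being modelled

Helical CT used for on-board image guidance sweeps its imaging plane along
the couch axis at constant speed.  Thoracic tumours breathe predominantly
along that same axis, so the reconstructed target is a set of
cross-sections sampled at different breathing phases — the interplay
effect.  Registering such a scan to the average reference CT (whose target
sits at the time-averaged position) incurs a longitudinal alignment error
that depends on motion amplitude, breathing rate, and table speed.  The
package simulates this error, summarises it into margin components, and
encodes the clinical decision rules built on top of those numbers.

## Breathing waveform

Displacement is 1-D (longitudinal, positive toward the head) and periodic
with period T = 60/rate.  Two shapes:

* **sinusoid** — d(t) = (A/2)·cos(2πt/T), A the peak-to-peak amplitude.
* **exhale_weighted** — a Lujan-type profile
  d(t) = A·(cₙ − sin²ⁿ(πt/T)) with cₙ = C(2n, n)/4ⁿ, the flat-topped trace
  of free breathing that dwells at exhale and dips briefly to inhale
  (default n = 2).  The centring constant cₙ makes the time average zero.

Both shapes are mean-centred, so the origin of the longitudinal coordinate
is the average-CT reference position; signed alignment errors are read
directly off the apparent-centre coordinate.  **Amplitude is peak-to-peak
by default** (the convention of programmable respiratory phantoms); a
`peak` convention flag is available because published motion figures are
sometimes half-excursions.  Start phase is a time offset, sampled uniformly
over one period by the experiment driver, since a scan begins at an
arbitrary point of the breath.

The default shape is the sinusoid.  The exhale-weighted profile is offered
because real free-breathing traces are exhale-dominant; no analytic form of
any particular phantom's programmed trace is claimed.

## Acquisition model

The simulator is a 1-D plane sweep, not an image reconstruction:

* Slice centres sit at (k + ½)·h on a scan length L (defaults h = 2.5 mm,
  L = 250 mm).  L is not a measured quantity; only the table speed L/scan
  time affects the interplay, and both are configurable.  Table speed is
  derived from the printed scan times (9.9 s standard, 59.5 s slow) rather
  than from pitch × collimation / rotation, because collimation is unknown;
  pitch and rotation time are retained as protocol documentation and for
  the rotation-window smear.
* Each slice is acquired when the plane crosses it: t_k = (distance from
  scan start)/speed, with the start at the superior end for head-to-feet
  scans and the inferior end for feet-to-head.
* Slice occupancy is the sphere's cross-sectional area
  π·max(r² − (z_k − c(t))², 0) at the acquisition instant, averaged over
  the gantry rotation window [t_k − rot/2, t_k + rot/2] by supersampling
  (default 11 samples).  This captures the finite temporal aperture of one
  rotation without modelling the sinogram.
* The **apparent centre** defaults to the area-weighted centroid of the
  occupancy — the centre of mass of the visible blob, which is what an
  operator centring a blurred target approximates.  A binary
  occupied-extent midpoint mode is available, but it over-weights the faint
  smeared tails of a partially averaged object: in testing it broke the
  observed monotone decrease of error with breathing rate and understated
  the standard protocol's variability, so it is not the default.
* The signed error (apparent centre − mean position) is optionally
  quantised to a readout granularity, default 1.0 mm, reflecting
  millimetre-granular clinical couch/manual readouts.  Sub-nanometre
  float residue is snapped to zero so symmetric configurations report an
  exact zero.
* Degenerate inputs raise: a sphere whose motion envelope misses every
  acquisition plane is `TargetNotCapturedError`, invalid
  protocol/waveform/config values are `ValueError` subclasses.

Two analytic limits pin the model.  In the snapshot limit (scan time ≪
period) the error equals the displacement at the instant the plane crossed
the sphere centre, so over uniform phase the mean absolute error of a
sinusoid is A/π.  In the averaging limit (sphere-crossing time ≫ period)
the occupancy averages the motion and the error tends to zero.  Both are
verified by seeded Monte-Carlo tests (10⁴ phases; the snapshot check uses a
synthetic 0.05 s protocol with 1 mm slices, the averaging check a 500 s
protocol, because the two clinical protocols sit between the limits —
the slow protocol crosses the sphere in only ~1–5 breathing periods).

## Factorial experiment

The default design is 2 protocols × {5, 10, 15} mm × {8, 20, 28}
breaths/min × 10 repeats = 180 scans, scan direction alternating
head-to-feet / feet-to-head within each condition and start phases drawn
uniformly from a single seeded generator.  The synthetic dataset generator
adds zero-mean Gaussian manual-alignment jitter (default SD 0.3 mm, well
below the 1 mm readout step) before quantisation.

## Margin model

Per condition, Σ is the mean of absolute longitudinal errors and σ their
sample SD (n − 1 denominator; the estimator choice is ours — summaries of
n = 10 make the difference ~5 %).  Absolute errors are used because the
guidance question is "how far off is the alignment", regardless of sign; a
signed mode is kept for sensitivity analysis.

Two recipes:

* quadrature baseline: 2.5·√(b² + Σ²) + 0.7·σ − offset, defaults b = 2 mm
  (patient/system systematic uncertainty, covering couch and image
  resolution) and offset = 3 mm;
* linear: 2.5·Σ + 0.7·σ − offset (the classic population recipe with an
  optional offset, default 3 mm).

Both appear in clinical use; they differ by how the 2 mm baseline enters
(the quadrature form exceeds the linear one by exactly 5 mm at Σ = 0 and
the same offset).  Reported margins are rounded half-up to 0.1 mm; exact
values are retained.

## Protocol statistics

Per condition, a two-sided Welch (unequal-variance) t-test compares the two
protocols' absolute-error samples.  The implementation computes t and the
Welch–Satterthwaite degrees of freedom from (mean, SD, n) directly, so the
test can be run from printed summary statistics; the raw-sample route is
definitionally identical and is cross-checked against an independent
library implementation in the tests.  Degenerate inputs (both variances
zero) return p = 1 for equal means and p = 0 with a warning otherwise.  No
multiple-testing correction is applied; p-values are per comparison at
α = 0.05, as the clinic uses them.  Note that with the bundled reference
summaries one condition has identical means in both arms, giving p = 1
exactly; "significant" is the strict inequality p < α throughout.

## Clinical workflow

Modality selection: CTOR iff amplitude ≤ 5 mm, or amplitude < 10 mm with
rate ≥ 20 breaths/min; otherwise MR-Linac.  The inclusivities are taken
verbatim from the clinical rule ("5 mm or less", "under 10", "20 or
greater").

Stability/re-imaging: the bone-vs-tumour difference must be < 5 mm on every
axis ("≥ 5 mm" triggers re-imaging).  After an unstable first image, the
second image must itself be stable **and** its longitudinal value must
agree with the first within 5 mm ("consistently less than 5 mm between the
first and second images" is interpreted as both conditions; this is an
interpretation, flagged as such).  A stable third image proceeds; anything
else escalates.  At most three images; a fourth, or imaging after the
procedure has already allowed treatment, is a protocol violation.  The
treatment value is the most recent image's longitudinal alignment for CBCT
and the mean over all images for CTOR.

## Synthetic cohort

Per-fraction longitudinal bone-minus-GTV differences are normal with mean
−1.9 mm and SD 1.7 mm (the published cohort summary); lateral/vertical
differences are zero-mean normal (SD 1.5 mm, a nominal residual-registration
scale).  Bone shifts are zero-mean normal with SD 3 mm per axis, a typical
thoracic setup-error scale, and the GTV shift is bone minus the drawn
difference so the difference distribution is exact.  Defaults: 31 patients,
4 fractions each.  Optional, off by default: a contaminating wide-normal
outlier component (to emulate range-scale extremes such as a −11 mm drift)
and a per-patient random intercept (default SD 1.0 mm when enabled) for
hierarchy-aware testing.  With both options off the marginal distribution
is exactly the stated normal, which the parameter-recovery tests rely on.

What the generators do **not** emulate: image content and contrast,
irregular or drifting breathing, 3-D motion, intra-course tumour volume
change, and any correlation between alignment error and breathing phase
beyond what the acquisition model produces.  Passing tests therefore show
that the pipeline's statistics and decisions are correct for data of the
assumed form — not that the simulator reproduces any particular scanner's
measured values, which are physical data.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁴ uniform start phases for the closed-form limits
(standard error ≈ 0.5 % of the mean, against a 2 % criterion) and 10³
repeats per condition for the trend checks; the cohort recovery test uses
10⁴ fractions (3-standard-error bands).  Waveform integrals use Simpson's
rule on 2×10⁵ + 1 points per period; tests compare against an independent
dense Riemann oracle.  All randomness flows from explicit
`numpy.random.default_rng` seeds; every CSV written by the CLI embeds the
seed and generator parameters in a `#` header comment, and re-running with
the same seed reproduces files byte-for-byte.

## Known limitations

The acquisition model is 1-D: no reconstruction artefacts other than
longitudinal apparent-shape distortion, no noise/dose model, no lateral or
anterior-posterior motion.  The apparent-centre model is a proxy for manual
soft-tissue alignment; real operator behaviour sits somewhere between the
centroid and extent-midpoint modes.  The readout granularity (1 mm) and
scan length (250 mm) are nominal configurable choices, not measured
quantities.  Margin recipes assume the usual population-margin conditions
(many fractions, normally distributed errors) that few-fraction SBRT only
approximately satisfies.
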