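# Methods

This note documents the models, estimators and design choices behind
`pushrim`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Court-sports wheelchair propulsion (the motivating case is para-badminton,
where one hand holds a racket while propelling) is characterized from
instrumented wheels that record, at 240 Hz per wheel, the wheel angle θ,
the three orthogonal contact forces Fx, Fy, Fz and the three moments Mx,
My, Mz applied to the handrim. The analysis answers two questions for a
paced straight-line protocol (20 m at 1.4 m/s):

1. *Per push*: how much force is applied, how fast it rises, and what
   fraction of it actually turns the wheel (propulsion effectiveness and
   injury-risk indicators).
2. *Per study*: how these parameters differ between design cells of a
   2×2 within-subject layout — condition (with vs without racket) ×
   side (dominant vs non-dominant hand).

## Signal chain

### Dynamic offset model

Rotating instrumented wheels carry angle-dependent baselines (gravity
acting on the sensing assembly). The full published cancellation
procedures are instrument-specific; `pushrim` uses a deliberately
simplified model per kinetic channel,

    offset(θ) = c0 + a·sin θ + b·cos θ,

fitted by least squares over *non-contact* samples and subtracted
everywhere. The non-contact mask comes from a provisional 30 N threshold
pass on the raw total force, eroded by 50 ms per side so boundary samples
of mislocated provisional pushes cannot leak into the fit. The fit
requires ≥ 100 masked samples spanning ≥ one revolution (identifiability
of the harmonic terms). The model is exact for any offset in
span{1, sin θ, cos θ}; higher harmonics and thermal drift are out of
scope and would appear in the reported per-channel residual RMS.

Offset removal is intentionally not idempotent (it subtracts the model
unconditionally); callers own the bookkeeping.

### Band-limiting and the two-band design

All six kinetic channels are zero-phase low-pass filtered (4th-order
Butterworth, applied forward–backward). Two bands are used:

- **Segmentation band, 20 Hz** (`lowpass_hz`): used for push detection
  and the temporal/ratio/integral metrics (PT, CT, PA, FEF, AI).
  Detection needs enough bandwidth that threshold crossings are not
  displaced.
- **Amplitude band, 12 Hz** (`amplitude_lowpass_hz`): used only for the
  max-type metrics (Ftot_peak, Mz_peak, PO_peak and the rate-of-rise
  derivative). The maximum of a noisy series is upward-biased by roughly
  the noise SD times the number of effectively independent samples near
  the peak; push waveforms live below ~6 Hz (a 0.35 s half-sine has its
  spectral mass under 3 Hz), so narrowing the band suppresses that bias
  without distorting the waveform. With white 2 N channel noise the
  unfiltered peak bias is ~2.5–3%; the 12 Hz band brings every amplitude
  metric's recovery error under 2% (verified in the acceptance suite).

Both cutoffs are configuration; `None` disables filtering, which is the
correct setting for noise-free synthetic validation (and is what the
closed-form tests use, together with a 5-sample derivative window).

### Wheel velocity

Angular velocity is the Savitzky–Golay smoothing derivative of the
cumulative angle: window 131 samples (~0.55 s at 240 Hz), polynomial
order 1, derivative order 1 — i.e. a sliding local-slope estimator.
Edges use the polynomial edge fit, which is exact for a linear angle all
the way to the boundary (true reflection padding would bend a ramp into
a tent and corrupt edge derivatives; edge pushes are excluded downstream
in any case, but exactness on constant-velocity segments is a useful
invariant). Linear velocity is ω times the wheel radius (0.3302 m for a
26-inch wheel). Trial velocity for pace checks averages the two wheels.

A consequence of the long window: in-push velocity fluctuation is
heavily smoothed, so peak-power estimates reflect the cycle-scale
velocity, not intra-push ripple. The synthetic generator therefore keeps
its in-push ripple small (0.1 rad/s ≈ 2% of mean ω) so that closed-form
peak power remains recoverable; with larger ripple the recovered PO_peak
would systematically miss the ripple contribution. This is a property of
the analysis definition (mandatory 131-point velocity filter), not of
the generator.

## Push segmentation

A push is a maximal run of samples with total force
Ftot = √(Fx²+Fy²+Fz²) ≥ 30 N. Two debouncing rules, both configurable:

- below-threshold gaps shorter than 50 ms are merged into the
  surrounding push (sensor chatter, brief grip adjustments);
- merged runs shorter than 100 ms are discarded (spikes). These are
  conservative relative to real push times (~0.34 s) and gaps (~0.8 s).

The threshold applies to the offset-corrected, 20 Hz-band total force.
The first two and the last detected pushes of each trial are excluded as
transitional (start-up from standstill, final coast); at least four
detected pushes are therefore required for any analysis.

Manual review of automatic segmentation is supported as a reproducible
edit-directive API (add / remove / adjust, each appended to an audit
log) rather than an interactive tool, so a reviewed analysis is still a
pure function of its inputs.

### Operational vs nominal push time

Threshold segmentation measures the *above-threshold* portion of a
push. For a half-sine of peak F and nominal duration PT, the detected
interval is shorter by the sub-threshold tails:

    PT_detected = PT · (1 − (2/π)·asin(thr/F)).

At F ≈ 85 N and thr = 30 N this is a ~23% difference — far from a
technicality. All ground-truth closed forms in the synthetic module are
therefore threshold-aware (RoR, AI and PA acquire the matching
√(1−(thr/F)²) factor); with thr → 0 they reduce to the ideal forms. A
corollary worth remembering when interpreting real data: raising the
peak force *lengthens* detected push time at fixed nominal duration,
which can mask or mimic genuine temporal changes.

## Outcome parameters (per analyzed push)

| name | definition | units |
|---|---|---|
| Ftot_peak | max √(Fx²+Fy²+Fz²) | N |
| Mz_peak | max propulsive moment | N·m |
| RoR | max dFtot/dt (SG derivative, order 2, 15 samples, amplitude band) | N/s |
| FEF | time-average of \|Ftan/Ftot\|·100, Ftan = Mz / r_handrim | % |
| PO_peak | max ω·Mz | W |
| AI | mean Mz × PT (= ∫Mz dt over contact) | N·m·s |
| PT | (end − start + 1)/fs, boundaries inclusive | s |
| CT | start-to-start to the next analyzed push (absent for the last) | s |
| PA | θ(end) − θ(start), in degrees | ° |

Choices that were genuinely open, and how they were resolved:

- **RoR**: defined as the maximum in-push derivative of Ftot, the usual
  convention in handrim kinetics; the alternative (peak force over
  rise time) is available as `ror_method="peak_over_rise_time"`. The
  derivative window (default 15 samples on the 12 Hz band) was chosen by
  a bias/variance analysis: shorter windows are noise-limited, longer
  ones truncate against the push onset where the true maximum lives.
- **FEF**: the tangential force is derived from the moment,
  Ftan = Mz/r_handrim — the standard instrumented-wheel derivation. The
  per-push summary is the time-average of the instantaneous ratio;
  ratio-of-means and value-at-peak variants are config-exposed
  (`fef_method`). Samples where |Ftan| exceeds Ftot raise a QC warning
  and are never clamped.
- **PO_peak**: power is ω·Mz with ω the *angular velocity* (the product
  has watts as units); the angle itself would be dimensionally wrong.
- **Mz sign**: propulsion is positive on both wheels after load-time
  normalization (left wheel flipped via a per-side flag); all-negative
  (braking) pushes warn but are kept.
- **PT convention**: boundaries are inclusive, PT = (end−start+1)/fs,
  documented so the ±1-sample quantization of every boundary-derived
  quantity (PT, CT, PA) is testable.

Trial summaries are arithmetic means over analyzed pushes per wheel
(CT over the pushes where it is defined), with the mean trial velocity
attached.

## Statistics

The comparison protocol, applied per parameter:

1. **Log transform.** All nine parameters are positive and right-skewed
   with multiplicative subject effects; tests run on natural-log values
   (the base only rescales sums of squares and changes no test).
   Shapiro–Wilk screening is available for reporting.
2. **2×2 within-subject ANOVA** (condition, side, interaction). The
   implementation partitions sums of squares explicitly: each effect is
   tested against its own effect×subject stratum,
   F = MS_effect / MS_(effect×subject) with (1, n−1) degrees of freedom.
   Partial eta-squared is SS_effect/(SS_effect+SS_error). With two
   levels per factor, sphericity is trivially satisfied and the
   Greenhouse–Geisser ε equals exactly 1; it is carried explicitly in
   the results rather than silently dropped. (Designs larger than 2×2
   are out of scope.)
3. **Paired t** (dominant hand, with vs without racket) on log values;
   Bonferroni adjustment over the post-hoc contrast family (default
   m = 2, the two within-condition side contrasts; configurable).
4. **Effect sizes.** Standardized mean differences are computed on the
   *untransformed* cell means and SDs, d = |m0−m1| / √((s0²+s1²)/2)
   (pooled SD), reported as absolute values to 3 decimals. This is the
   form under which every reported d is reproducible from the report
   table's own printed cells — a self-consistency property the test
   suite enforces on generated reports and verifies against the bundled
   reference table. The literal reference-group-SD form
   (divide by s0) is available as `d_method="reference_sd"` but is not
   self-consistent with pooled-SD tables. Verbal bands follow Cohen:
   d = 0.2/0.5/0.8 and η²p = 0.01/0.06/0.14, thresholds inclusive.

The ANOVA is validated three ways: against a brute-force cell-mean SS
decomposition written independently (agreement to 1e-10), against the
F = t² identity for two-level factors (1e-9), and against `pingouin`'s
two-way repeated-measures ANOVA.

## Synthetic data: what it emulates, and what it does not

`generate_trial` synthesizes one wheel's recording: half-sine total
force pulses (peak ~95 N, 0.35 s, 1.2 s cycle by default — centered on
the regimes reported for paced 1.4 m/s court-chair propulsion), constant
tangential fraction per push (Mz = tf·Ftot·r_handrim), the non-tangential
force split 80/20 (squared magnitude) between in-plane radial and
out-of-plane components so the three channels reconstruct Ftot exactly,
angle integrating ω = v/r plus a small analytically-integrated in-push
ripple, then additive white Gaussian sensor noise (2 N on forces,
2·r_handrim N·m on moments) and optional angle-dependent offsets.
Push-to-push, between-subject and trial-level variability are all
multiplicative lognormal (median-preserving), matching the
log-transformed analysis. Every generated push carries closed-form
ground truth for all nine parameters, threshold-aware as described
above.

`generate_study` builds the full 2×2 design: lognormal subject random
effects (default CVs: peak force 0.35, tangential fraction 0.20, push
duration 0.15, cycle duration 0.25, speed 0.03), multiplicative
condition/side/interaction effects per profile field, one trial per
condition with both wheels synthesized, a manifest written to disk if
requested. Realized per-cell peak force is floored at 45 N so every
simulated wheel stays detectable at the 30 N threshold (a participant
who cannot clear the threshold would contribute no analyzable pushes in
a real study either). The `racket_effects()` preset injects the
directional with-racket pattern (stronger but less effective dominant
side); its push-duration multiplier (0.89) is calibrated for the
*operational* push time, compensating the threshold-geometry effect of
the simultaneously raised peak force.

`simulate_parameter_studies` is the fast path for calibration
experiments: it samples per-trial parameter summaries directly from the
same lognormal model (subject effect × cell effect × i.i.d. trial
noise) and skips waveform synthesis. Type-I error and power depend only
on the panel distribution, so 2,000-replicate calibrations run in
milliseconds instead of hours; waveform-level and parameter-level paths
are cross-checked at small replicate counts by the test suite's
end-to-end runs.

What the generator does **not** model: non-half-sine push morphology
(double peaks, braking dips), rolling resistance and deceleration
between pushes, camber mechanics, hand repositioning chatter,
instrument drift beyond the first angular harmonic, or any
musculoskeletal content. Passing recovery tests therefore demonstrates
correctness of the *pipeline* under the stated signal model, not
validity of the signal model for any particular athlete.

## Numerical conventions

- Problem sizes in the validation suite: 50 trials for noisy parameter
  recovery, 100 random panels for the ANOVA oracle, 2,000
  parameter-level replicates for type-I calibration, 100 waveform-level
  replicates (n = 16, 12 pushes per trial) for directional-pattern
  recovery — sizes at which the Monte-Carlo error of each check is an
  order of magnitude below its tolerance.
- Temporal quantities are quantized at one sample per detected
  boundary; tests use sample-resolution tolerances (2 samples for PT,
  CT, and the corresponding angle for PA), not relative ones.
- Report tables round means/SDs to 2 decimals and d/η²p to 3; machine
  outputs keep full precision. Re-running the pipeline on identical
  inputs and configuration is byte-identical.
- Degenerate inputs fail loudly with typed exceptions (NaN channels,
  constant Shapiro–Wilk input, zero-variance paired differences,
  in-push zero total force, incomplete design cells); nothing is
  interpolated or clamped silently.

## Known limitations

- The offset model is a first-harmonic simplification of published
  instrument-specific procedures; recordings with strong higher-order
  offset harmonics would leave structure in the coast-phase residuals.
- FEF from Mz/r assumes all moment about the axle comes from tangential
  hand force (no hand-torque contribution).
- The RoR estimator's defaults are matched to 240 Hz recordings with
  ~2 N white noise; substantially different instruments warrant
  revisiting `ror_window` and the amplitude band.
- With only two levels per factor the Greenhouse–Geisser machinery is
  vacuous (ε = 1); reporting it maintains interface compatibility, not
  statistical content.
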