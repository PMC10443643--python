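# Methods

## Signal model and preprocessing

A raw channel is modelled as `I(t) = DC(t) + AC(t) + noise`: a slowly varying
baseline intensity (posture, venous volume, drift) carrying a cardiac
pulsatile component of roughly 1–3% relative amplitude. The pipeline
undersamples every channel to a common 100 Hz (polyphase FIR resampling,
`padtype="line"` so constants and edges are preserved), then separates the
components with 2nd-order Butterworth filters: 0.8–10 Hz band-pass for AC,
0.1 Hz low-pass for DC. The analysis signal is `ac/dc × 10`, dimensionless
and invariant to detector gain.

Filters are applied forward–backward (zero-phase). Morphology features
depend on fiducial timing, and causal filtering would delay the systolic
peak and bias rise/decay times; the cost is a squared magnitude response
(6 dB attenuation at each nominal cutoff), which the tests account for: the
zero-phase amplitude gain equals `|H|² = 1/(1 + X⁴)` for the order-2
Butterworth prototype. A settling guard of `3 / 0.8 Hz = 3.75 s` at each
record end is excluded from beat detection.

The positivity floor for the normalization divisor is `1e-6 × median|dc|`;
values at or below it raise an error naming the first offending index, so
the failure mode is deterministic rather than an inf propagating silently.

## Synthetic recordings

The generator emits the *stated world* the analysis assumes, not a
photon-transport simulation. Each beat is a two-lobe raised-cosine template
over cycle phase: a systolic lobe centered at the rise fraction (0.3) whose
half-width equals `rise_fraction × width` (so the template is anchored at
zero at phase 0 for `width ≤ 1`), and a diastolic shoulder (relative height
0.3, centered at phase 0.6) standing in for the dicrotic wave. The cycle
maximum equals the amplitude parameter exactly, and the area under one cycle
is linear in the width parameter while both lobes fit inside the cycle —
the properties the template tests pin down.

Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| native sample rate | 500 Hz | above 100 Hz so undersampling is exercised |
| heart rate | 70 bpm, 3% cycle jitter | resting adult |
| pulse fraction | 2% of DC | typical perfusion-scale pulsatility |
| DC levels | supine 5.0, Trendelenburg 5.5 a.u. | venous engorgement raises baseline |
| Valsalva DC ramp | +15%, 0.3 s edges | abrupt strain onset/release |
| additive noise | 0.05 × pulse amplitude | clean laboratory recording |
| condition effects (distal) | amplitude ×1.3, width ×1.15 | enlarged flow pulsatility under raised ICP |
| proximal attenuation | 0.3 | proximal = extracerebral share of the effect |
| respiratory modulation | 8% amplitude / 4% width at 0.09 Hz | respiratory/Mayer-band variability |
| very-low-frequency modulation | 10% amplitude at 0.015 Hz | window-scale variability |
| between-subject heterogeneity | amplitude sd 0.10, width sd 0.05, heart-rate sd 0.08 | makes subject-wise validation non-trivial |

The proximal channel receives each multiplier attenuated toward 1 by a
single scalar (`1 + 0.3·(m − 1)`), modelling distal = extracerebral +
cerebral, proximal = extracerebral only. Transitions between tilting
positions carry a linear DC ramp and unmodified pulses. All randomness flows
through one generator seeded from `(seed, crc32(subject_id))`; identical
inputs reproduce recordings bitwise.

The physiological-modulation fields are part of the stochastic model with
nonzero defaults; the "no noise ⇒ identical morphology across conditions"
contract is therefore exercised with those fields set to zero explicitly,
while with defaults the null contract is distributional (window medians in
event windows match baseline on average).

What the generator does **not** emulate: motion artifacts, optode-coupling
changes, arrhythmia, oxygenation-dependent multi-wavelength structure, and
any photon-transport realism. A green pipeline test establishes that the
algorithms recover the structure this world contains — not that the sensor
works on real foreheads.

## Sectioning

**Tilting** is metadata-driven. With nominal durations (300, 300, 120) s and
2 transitions, the average transition is `t = (total − 720)/2`; position
windows are laid out with one transition between consecutive positions and
each section keeps the middle 60% (trimming 20% per side). Real transitions
are unequal but the algorithm, by construction, only knows their mean; the
trimming absorbs the resulting misalignment.

**Valsalva** is signal-driven. First and second discrete derivatives of the
normalized signal are smoothed with a Savitzky–Golay filter (0.51 s window,
order 3 — beat-scale smoothing; neither value is prescribed anywhere, both
configurable). Envelopes interpolate linearly through local extrema of the
first derivative separated by ≥ 0.4 s (beat scale). A strain onset makes the
band-passed DC step spike the upper envelope; the release spikes the lower
envelope. The detector takes envelope maxima (≥ 10 s apart, above 1.8 × the
median envelope, outside a 4 s settling guard) highest-first, and accepts a
candidate only if a qualifying lower-envelope minimum follows within
5–25 s — the maneuver-scale duration bound. Window boundaries snap to the
nearest crossing of the first and second derivatives within 2 s. The
baseline segment has the mean detected event duration and ends 5 s before
the first event.

Two deliberate readings of ambiguous prose: "maximum lows" are resolved
per event (deepest lower-envelope minimum in the span following each
onset) rather than as a global top-3, because a sharp release transient has
a ringing sibling lobe near the *start* that a global selection can latch
onto; and the onset/release pairing is one consistent interpretation among
several. Event-free records fail with "insufficient events" — the envelope
of a pulse-only signal stays near its median, far below the 1.8× threshold.

## Features

Beats are systolic peaks (local maxima ≥ `60/180 bpm` apart with prominence
≥ 0.3 × the median prominence) with onsets at the minima between consecutive
peaks; the first and last partial beats are dropped. Per beat, with the
baseline defined as the straight chord joining the signal at onset and end:
F1 is peak minus baseline; F5/F4 rise/decay times; F3 = F1/F5 (chord slope,
not maximum derivative — a documented convention); F2 the width at 50% of
F1 with linear interpolation at the crossings; F6/F7/F8 trapezoidal areas of
the baseline-corrected, non-negative-clipped pulse with the
systolic/diastolic boundary at the peak (the dicrotic notch is not
detected); F9 = F7/F8. F6 is computed as F7 + F8 — the interval splits
exactly at the peak, so the identity is structural. Beats with a
non-positive F1 or zero F8 are excluded.

Windows tile each section independently (15 s tilting, 5 s Valsalva,
non-overlapping), beats are assigned by peak time, a median needs ≥ 3 beats,
and trailing partial windows are dropped.

## Statistics

Window-level medians are treated as independent observations — the analysis
convention this package reproduces; no subject-level random effect is
fitted, which overstates degrees of freedom when windows within a subject
correlate (known limitation). Assumption checks never gate anything
automatically; `boxcox="auto"` transforms the factorial-model response only
when a normality or Bartlett check fails at α, with `always`/`never`
available for reproducibility studies. The Box–Cox shift is
`max(0, 1e-6·range − min)` so already-positive data are untouched, and λ is
chosen by maximum likelihood. Type II sums of squares are used because the
window counts per section are unbalanced by construction (they coincide with
Type I in balanced designs — tested). No multiple-testing correction is
applied across the nine features, matching the reproduced analysis; a
Bonferroni column is reported alongside. The tilting contrast pools
supine1 + supine2 as "supine" by default (flag to restrict to supine1).

Mann–Whitney U uses exact enumeration for no-tie samples with min(n) ≤ 8
and the tie-corrected normal approximation otherwise; Kruskal–Wallis returns
H = 0, p = 1 for all-identical data instead of an error.

## Classification

`prepare_dataset` keeps distal 810 nm rows, binarizes (Trendelenburg vs
pooled supine; any Valsalva window vs baseline), undersamples the majority
class per subject without replacement (seeded), and min–max scales over the
whole prepared dataset — the pre-processing order this reproduces, which
leaks scaling statistics across folds; `strict_scaling=True` refits the
scaler per training fold. The logistic model carries a small L2 ridge
(scikit-learn default C = 1) so perfect separation on small folds cannot
diverge; the decision threshold is fixed at 0.5. LOSO yields one fold per
subject; k-fold is a seeded row-level shuffle (subjects span folds, so
k-fold scores are optimistically biased relative to LOSO — reported, not
hidden). Fold metrics with an absent class are NaN, excluded from averages
and counted.

## Numerical choices and degenerate inputs

- Section boundaries round seconds to the nearest sample; lengths match the
  keep-fraction within ±1 sample.
- Resampling uses a rational approximation of the rate ratio
  (`limit_denominator(10000)`); upsampling is refused.
- Constant signals: band-pass returns ~0, beat detection returns an empty
  list, envelope construction returns flat envelopes, normality tests return
  NaN with a note.
- Determinism: every stochastic step (generation, undersampling of the
  majority class, k-fold shuffle) takes an explicit seed; the pipeline
  manifest records all of them plus SHA-256 of every artifact, and a rerun
  from the manifest is byte-identical.

## Limitations

- Window medians are pseudo-replicates; subject-level inference would need a
  mixed model.
- The synthetic effect sizes are stand-ins: classification scores on this
  world calibrate the *pipeline*, and only the qualitative distal > proximal
  ordering — not the absolute percentages — is meaningful.
- The Valsalva detector keys on strain-edge transients; maneuvers with slow
  onsets (ramps ≫ 1 s) would weaken the envelope spikes it relies on.
- Only the 810 nm isosbestic wavelength is analysed; other wavelengths pass
  through the containers but are filtered out before modelling.
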