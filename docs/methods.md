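# Methods

This note documents the models, numerical choices, and limitations behind
`pttbp`: what the pipeline computes, what the synthetic-data generator does
and does not emulate, and where the design was genuinely open.

## The measurement model

Pulse transit time is measured per task (protocol segment) as
`PTT = foot − AO`, where both fiducials are read off ensemble-averaged
beats:

* the **PPG diastolic foot** by the intersecting-tangent construction: the
  tangent at the point of maximum first derivative on the systolic upstroke
  is intersected with the horizontal line through the preceding local
  minimum.  The tangent point is located on the centered first difference
  and refined to sub-sample resolution with a three-point parabola; the
  intersection itself is exact line algebra, so the result is continuous in
  time.  The foot, not the systolic peak, is used as the distal reference
  because the peak's timing is confounded by wave-reflection interference.
* the **SCG aortic-valve-opening (AO) point** as the earliest local maximum
  (prominence ≥ 10 % of the beat's peak-to-peak amplitude, parabolic
  sub-sample refinement) inside a physiologic pre-ejection-period window,
  default [0.03, 0.15] s after the R-wave, and before the PPG foot.  Manual
  annotation in practice serves two purposes we reproduce mechanically: the
  PEP window constrains the search, and an optional *consistent-morphology
  mode* re-picks, per task, the candidate peak closest to the participant's
  median first-pass AO latency so the same peak is used across tasks.

The pulse arrival time `PAT = PEP + PTT` (R-wave to foot) is what the gate
checks against a realistic range, default [0.10, 0.50] s.

Per participant and BP component, calibration is ordinary least squares of
the reference BP on PTT⁻¹ (`BP = K1/PTT + K2`), one calibration point per
kept task: the PTT of the selected ensemble paired with the min / max /
time-average (DBP / SBP / MAP) of the highest-SNR averaged ABP beat.  At
least four tasks are required; nonlinear models would demand more
calibration points than a per-participant protocol provides.

## Processing chain and its parameters

| stage | default | why |
|---|---|---|
| ECG band-pass | 10–40 Hz FIR | isolates the R-wave, removes postural drift |
| SCG band-pass | 1–40 Hz FIR | keeps the AO complex, removes respiration |
| PPG band-pass | 1–8 Hz FIR | pulse waveform band, removes baseline wander |
| ABP smoothing | 50 ms moving average | suppresses cuff-servo ripple; mean-preserving |
| ensemble window | 10 beats, hop 5 (50 % overlap) | √10 noise reduction at beat-level stationarity |
| PPG selection | top-10 % upstrokes (⌈0.1·M⌉, min 1), then max SNR | steep upstrokes mark well-perfused, well-coupled beats |
| SNR | 10·log₁₀(P_avg / P_residual), capped +60 dB | residual power about the ensemble mean as the noise estimate |
| gate | all three SNRs ≥ thresholds and PAT in [0.10, 0.50] s | inclusive comparison so capped-SNR (noise-free) windows pass |
| PEP window | [0.03, 0.15] s | physiologic pre-ejection-period range |

FIR filters are Hamming windowed-sinc band-passes of order
min(4·fs/f_lo, 4000) with an odd tap count (type-I linear phase); the
integer group delay is removed after convolution, so interior samples see a
zero-phase response and symmetric waveform features keep their timing
exactly.  The residual DC gain of the windowed design is zeroed by
subtracting the tap mean (< 1e-4 passband perturbation).  The 4·fs/f_lo
order keeps the transition band narrower than the low edge itself; at the
1 Hz edge this costs a 4 s impulse-response span, which is why sessions
carry a 2 s lead-in pad and the pipeline skips the first second of every
task (see gating).

The moving average uses shrinking windows at the edges rather than invented
padding.  R-peaks come from an adaptive threshold (half the rolling 2 s
maximum) with a 250 ms refractory period — supporting up to 240 bpm — at
the 1 ms resolution of the 1 kHz grid; sub-sample R timing is unnecessary
because PTT is a *within-beat* difference and cancels the beat-start
quantization.

**Alignment.** The wearable and reference streams are aligned on their
ECGs: R-peak trains (widened to ±10 ms triangles to tolerate detection
jitter) are cross-correlated and the lagging group trimmed.  The search
window, default ±0.5 s, is deliberately kept below one R-R interval so the
periodic aliases of the beat train cannot win; within the window, a
competing lag reaching 99 % of the maximum raises an ambiguity error rather
than silently picking one.

**Gating.** Thresholds are participant-specific: the larger of an absolute
per-channel floor (PPG 5, SCG 0, ABP 20 dB) and a quantile (default 25th)
of that participant's own window SNRs.  If fewer tasks survive than the
calibration minimum, the quantile component is relaxed stepwise
(0.25 → 0.15 → 0.05 → 0) — never below the floors — mirroring how
per-participant cutoffs are set in practice so that at least four tasks
remain usable.  A channel that cannot clear its floor (e.g. an SCG drowned
in noise) still renders the participant uncalibratable.  Because
hemodynamics and filter state are both in transition at task boundaries,
beats in the first second of each task (configurable) are excluded from
windowing.

## The synthetic-data generator

The generator's role is *verifiability*: it produces sessions whose
fiducial times, task-level BP, and calibration coefficients are known
exactly, under the statistical structure the analysis assumes.

**Ground-truth law.** Each participant carries (K1, K2) per BP component
and a per-task inverse-PTT profile; task BP values are derived from the law
(`BP_c = K1_c·PTT⁻¹ + K2_c`), which makes all three components exactly
consistent with the single PTT the device measures — the only construction
under which per-component coefficient recovery is well-posed.  Defaults:
DBP K1 = 2.0 mm Hg·s, K2 = 60 mm Hg, with MAP/SBP slopes and intercepts
offset by fixed increments (+0.8/+1.6 mm Hg·s, +15/+32 mm Hg) chosen so
that DBP ≤ MAP ≤ SBP holds at every task and MAP sits at ≈ 0.45 of pulse
pressure.  The default task profile spans 1/PTT from 3.5 to 14.5 s⁻¹
(PTT 69–286 ms), i.e. a ≈ 30 mm Hg MAP range across tasks — calibration
needs a large BP dynamic range.  `random_law()` draws DBP coefficients
uniformly on K1 ∈ [1, 3] mm Hg·s, K2 ∈ [50, 75] mm Hg and widens the task
profile to keep the MAP span ≥ 25 mm Hg within physiologic PTT.

**Schedule.** The default protocol is sitting and standing baselines
(120 s each) followed by 60 s measurement segments: rest, post-mental-
arithmetic, post-cold-pressor, and early/late exercise recovery.  Segment
labels name the perturbation whose after-effect they measure; no PTT is
recorded during exercise itself, so no exercise segment is scheduled by
default.  Task BP is constant within a segment — the generator models the
settled post-perturbation state, not the transient.

**Waveforms.** Morphologies are deliberately simple and chosen for exact
analyzability rather than physiological detail:

* *ECG*: a symmetric Gaussian R-wave (σ = 8 ms) plus a small T-wave; a
  symmetric bump keeps its apex under zero-phase filtering.
* *SCG*: a Gabor burst (20 Hz carrier, σ = 18 ms) centred at R + PEP.  The
  envelope peak coincides with the carrier maximum, so the AO truth is the
  burst centre; side lobes stay below the 10 % prominence floor, and the
  burst's spectrum (≈ 11–29 Hz) passes the 1–40 Hz band unchanged.
  PEP defaults to 60 ms, constant within a session.
* *PPG*: built in the frequency domain from harmonics 2…K of the heart
  rate, with K capped so every component stays below 6.9 Hz — inside the
  flat region of the 1–8 Hz analysis band — and the fundamental *excluded*
  because it falls in the high-pass transition band.  A waveform with this
  spectrum passes the pipeline's own filter essentially unchanged, so the
  constructed geometry survives preprocessing.  The harmonic phases are
  then calibrated (by measuring the template with the package's tangent
  routine and shifting, exact in the harmonic domain) so the intersecting-
  tangent foot lands exactly at R + PEP + PTT.  The three wavelengths share
  this timing and differ only in amplitude (IR 1.0, red 0.6, green 0.3 by
  default), emulating the melanin- and BMI-dependent optical penetration
  that makes IR the most reliable wavelength.
* *ABP*: a normalized pulse of raised-cosine transitions between flat
  plateaus at the true DBP and SBP, with the systolic-plateau width solved
  so the time average equals the true MAP.  Plateaus are kept wider than
  the 50 ms smoothing window, so the moving average preserves the extrema
  exactly and (being mean-preserving) the MAP too.

Beats are placed at R times with normally distributed R-R jitter
(mean 60/HR, HR default 70 bpm, SD 3 bpm); each beat renders the nominal
waveform with the jitter absorbed by stretching only the beat's tail, so
the fiducial-bearing early portion is untouched.  Noise is additive white
Gaussian per channel, plus Poisson-timed motion bursts (default
0.5 min⁻¹, 0.5–2 s, 10× the channel SD, band-limited and tapered) on the
wearable channels.  The reference channels are delayed by a configurable
integer lag (default 150 samples) to exercise the alignment stage.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic ECG/SCG/PPG morphology variability,
respiratory and autonomic modulation of PEP and pulse shape, BP transients
within tasks, baseline wander beyond what the filters remove, sensor
nonlinearity and saturation, and true inter-beat waveform correlation of
artifacts.  Agreement numbers on synthetic cohorts certify the *pipeline's*
correctness, not device accuracy in humans.

## Statistics

Agreement is summarized by MAD, RMSE, Pearson correlation (flagged
undefined for constant inputs), and Bland–Altman bias ± 1.96·SD limits of
agreement (both half- and full widths are exposed, since "95 % interval"
conventions vary).  The MAD maps to the wearable cuffless-device grades
A ≤ 5, B ≤ 6, C ≤ 7 mm Hg, else D; the table lives in configuration.

Demographic comparisons of the DBP coefficients stratify by obesity
(BMI ≥ 30 kg/m², the NHLBI cutoff), sex, race (Black vs other), and age
(< 40 vs ≥ 40 years; the conventional brackets are "≤ 40" and "≥ 40",
which double-count exactly 40 — we assign it to the older group).  Each
group gets a one-sample Kolmogorov–Smirnov normality check against a
normal law with sample-estimated moments (a Lilliefors-corrected variant is
available; the plain KS is anti-conservative with estimated parameters, so
it errs toward treating data as normal).  Group differences use the
Mann–Whitney U test for these unpaired groupings and the Wilcoxon
signed-rank test for paired ones (per-participant wavelength comparisons).
Tie-free samples with n ≤ 12 use exact enumeration p-values; larger or
tied samples use the tie-corrected normal approximation.  The two-sample
t test from summary statistics uses the pooled-variance form.  No
multiple-testing correction is applied across the comparison battery.

Operating characteristics (type-I error, power) of the group comparison
are studied at the coefficient level: `simulate_cohort(signals=False)`
samples per-participant laws and demographics without synthesizing
waveforms, since the signal chain recovers coefficients to ≈ 0.01 % and
contributes nothing to the test's distribution.  Replicated cohorts at
n = 20/20 put the empirical type-I rate inside the binomial band of
α = .05 and the power at ~100 % for a 4-SD K1 effect.

## Problem sizes and determinism

The test suite and the acceptance script scale the studies to desk size as
the package's own defaults for automated verification: 20-participant
noise-free recovery cohorts with 20 s tasks, 100-law (tests) / 30-law
(script) fiducial sweeps with three 15 s tasks, three full-protocol
sessions at 10 % noise, 100-seed Monte Carlo for the averaging law, and
200/100 replicate cohorts for the operating characteristics.  Every random
draw flows from one `numpy` Generator seeded by the caller; identical
seeds give identical sessions, and the pipeline itself is deterministic
given a session and a configuration.

## Known limitations

* The SNR definition (averaged-beat power over member-residual power) is a
  documented stand-in for the externally published noise-detection
  algorithm the field uses; it is config-swappable.
* Exact numeric SNR cutoffs and the "realistic" PAT range used in practice
  are unpublished; both are configuration parameters here.
* K1 is reported in mm Hg·s (the dimensionally consistent unit for a slope
  against PTT⁻¹); printed "mm Hg/s" values elsewhere are numerically
  comparable.
* The calibration is per-participant and task-level; population-level
  calibration, recalibration intervals, and PEP estimation from other
  modalities are out of scope.
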