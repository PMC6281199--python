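# Methods

`alphaloop` models a closed-loop analog neurostimulation experiment — an
inverting band-pass filter feeding a cortical alpha rhythm back into the
brain as phase-locked transcranial current — and re-implements the offline
LFP analysis used to quantify its after-effects. This note records the
models, the parameters that matter, and the numerical choices, in enough
detail to reproduce or criticize any number the package produces.

## The feedback chain

The filter is a single-stage multiple-feedback (MFB) second-order band-pass
with equal capacitors. With input resistor R1, feedback resistor R2, shunt
resistor R3 and capacitance C,

    H(s) = -(s / (R1 C)) / (s^2 + (2 / (R2 C)) s + (R1 + R3) / (R1 R2 R3 C^2)),

so the center frequency, quality factor and midband gain are
ω0² = (R1+R3)/(R1 R2 R3 C²), Q = ω0 R2 C / 2, A0 = −R2/(2 R1). `design_mfb`
inverts these relations for a requested (f0, Q, |A0|, C); realizability
requires 2Q² > |A0| (otherwise R3 ≤ 0). The canonical alpha design is
f0 = 12 Hz, Q = 1.5 — an 8 Hz passband covering 8–16 Hz. The topology is
naturally inverting, so the stage contributes 180° of phase at f0, rising
to ~185° just below center.

The rest of the chain (head-stage amplification, digitization, DAC) is
modeled as a pure delay, 42 ms by default, contributing 360·f·delay degrees
— 175° at 11.6 Hz. The total loop phase of the canonical design crosses
360° near 11.6 Hz (the model gives 361.2°), which makes the loop *positive*
feedback for the alpha rhythm: the stimulation arrives nearly in phase with
the oscillation it was recorded from, one cycle late. A reported total of
372° at 12 Hz is not reproducible from a pure second-order stage plus pure
delay (the model gives 361.4°); the package treats the 360°-at-11.6 Hz
statement as the binding characterization of the chain.

Discretization uses the bilinear transform with frequency pre-warping at
f0, which pins the discrete center-frequency response (and hence the 180°
phase) to the analog value; at 1 kHz sampling the discrete response matches
the analytic one to well under 1% magnitude and 2° phase across 5–30 Hz.
`apply_filter` is causal: filter, integer-sample delay, then hard clipping
at the command limit (±0.5 V, i.e. ±1 mA at the stimulator's 2 mA/V gain).

## The oscillator plant

There is no accepted biophysical model for how transcranial current
perturbs an alpha generator, so the simulator uses the simplest process
with a spectral peak and a meaningful phase: an AR(2) resonator (sampled
damped harmonic oscillator) driven by white noise, plus 1/f background.
Defaults: natural frequency 11 Hz; damping ζ = 0.015 (ring-down time
constant ≈ 1 s at 11 Hz, long enough for post-offset after-effects to be
measurable); drive noise chosen so the free-running rhythm is ~100 µV RMS
over a 25 µV RMS 1/f floor. Stimulation current enters as additive drive
through a single `coupling` constant (drive units per ampere) — electrode
and tissue transfer are identity; the package cannot and does not
distinguish additive drive from excitability modulation. Coupling defaults
to 60, a value chosen at design time to put the closed-loop gain near 0.5–0.8
at resonance, so that a 10 s feedback trial changes alpha power by around
+1 dB (constructive) or −0.5 dB (destructive) — resolvable within a
16-trial session. Real effects reported for brief stimulation are an order
of magnitude smaller; the simulator's louder loop trades realism of scale
for a sign that is testable per seed.

The interference experiment (`post_offset_alpha_change`) runs the closed
loop and a free-running plant on *identical* noise (same seed) and
compares mean 8–15 Hz band power in the first second after each of 16
stimulation offsets. The band power here is a zero-phase Butterworth
measure, not the multi-trial median pipeline, because the matched
comparison is between two single realizations, for which the across-epoch
median steps are degenerate. With the canonical design the un-inverted
loop raises post-offset alpha and an extra 180° (sign flip) lowers it;
this sign pattern is the simulator's headline property.

## The synthetic-session generator

The statistical generator builds sessions with exactly the structure the
analysis assumes, with no dynamics. Arrays are 96-electrode grids (10×10
minus corners); one adjacent pair on Array 1 is the bipolar controller.
Each channel is: per-channel 1/f noise (50 µV RMS, exponent 1) plus an
alpha rhythm synthesized as 8–15 Hz band-passed Gaussian noise (75 µV RMS
total) — a narrow-band *process*, not a sinusoid, because measured
post-stimulus changes are broad-band across alpha. Rhythm power is split
50/50 between a component shared across the array and a per-channel
component. Perfect inter-electrode coherence would make electrode
averaging a no-op; electrodes millimetres apart see partially coherent
alpha, and 0.5 shared power is a deliberate, fixed middle ground. Channel
gains jitter by 10%.

Trials follow the experimental schedule: nominally 10 s of stimulation
(realized duration uniform on 7.74–10.74 s, mimicking stopwatch control),
40 s rests, blocks of 10 per condition, 120 s between blocks. During each
stimulation the single-ended channels are clamped to an amplifier rail
(±3000 µV); the bipolar controller pair stays clean. Event times mark
desaturation: immediate in vivo; in the saline generator the offset event
lags the nominal stimulation end by 3–9.5 s (uniform), reproducing the
slow bath desaturation that the 20 s in-vitro rejection limit accommodates
and the 11 s in-vivo limit does not. The saline generator carries no
oscillatory component at all.

Ground-truth effects multiply one band's power by 10^(dB/10) on every
channel of one array for a fixed interval after each offset of one
condition. The injection scales the band-limited component extracted with
a flat-passband linear-phase FIR widened ~1 Hz (3 Hz for high gamma)
beyond the nominal band, so that the discrete wavelets at the band edges —
whose spectral support extends ~1 Hz past the boundary — see fully scaled
content; power strictly inside the band scales exactly. Recovery studies
use a 1.5 s effect so that the 0.5–1 s summary window plus the wavelet
support sits inside the perturbed interval; a perturbation shorter than
the wavelet's 1 s span cannot be recovered without deconvolution, which
the summary statistic does not attempt.

## The analysis pipeline

Trials whose onset→offset time exceeds 11 s (in vivo) or 20 s (in vitro)
are rejected; the controller pair and flagged-bad channels are dropped. No
artifact correction is applied anywhere — rejection only. Epochs run −5 to
+5 s around onsets and offsets (half-open at sample resolution, 10 000
samples at 1 kHz).

Morlet wavelet power uses a family rising linearly in both frequency
(5–30 Hz, 1 Hz steps) and cycles (5–30, index-matched), which makes every
wavelet span exactly one second (σ_t = 1/2π s); power is the squared
magnitude of the complex convolution (MNE's L2-normalized wavelets, so
white noise has frequency-independent expected power). The high-gamma
family (80–200 Hz, 5 Hz steps, cycles = f/2, a fixed 0.5 s span) is this
package's own construction — no low-frequency family extends there — and
high-gamma results are validated only property-wise. The transform is
computed on the onset and offset epochs separately; the stimulation period
is then excised *in the power domain* by keeping the pre-onset half and
the post-offset half, so no concatenation seam ever passes under a
wavelet. Samples within half a wavelet of an epoch edge are flagged
invalid rather than dropped.

Normalization, per wavelet frequency: (1) divide each epoch by its own
median power over edge-valid times; (2) take the median across epochs at
each timepoint; (3) divide by the grand median of the −5…−1 s baseline
(valid columns only); (4) convert to decibels (10·log10). Restricting the
medians to edge-valid samples matters: edge-attenuated columns would drag
the baseline median down and bias every post-stimulation estimate upward.
Band power is the arithmetic mean of the dB traces over the band's
discrete frequencies, endpoints inclusive (alpha 8–15, beta 15–30, high
gamma 80–200; 15 Hz belongs to both alpha and beta, as the definitions
read); electrode aggregation likewise averages in dB. The summary is the
time-mean over 0.5–1.0 s after offset (0.5–1.5 s as a robustness window).

Resampling recomputes steps 2–4, the band mean and the window mean inside
every draw. `bootstrap_vs_zero` resamples trials with replacement (5000
default) and reports the confidence-distribution masses above and below
zero; the headline p is two-sided, 2·min(mass above, mass below) capped at
1, with both one-sided masses in the output. `perm_condition` permutes
condition labels over the pooled trials, two-sided p as the fraction of
|null| ≥ |observed|, with no small-sample (+1) correction; when group
sizes differ, the larger group is subsampled to the smaller within every
permutation. `perm_array` shuffles electrode→array assignment and
compares array means — the unit of exchange is the electrode. All schemes
switch to exhaustive enumeration when the permutation space is no larger
than the requested draw count. BH-FDR is applied within each band's family
of three tests (statsmodels' step-up implementation).

## Numerical choices

* Power time axis is decimated tenfold (100 Hz) before normalization; the
  wavelet envelopes change over hundreds of milliseconds, so band summaries
  are unchanged to well under 0.01 dB.
* Inside resampling draws the baseline grand median may be computed on a
  strided subgrid of baseline columns (stride 4 in the scaled studies);
  neighbouring 100 Hz power columns are nearly redundant, and the across-
  trial medians are collapsed trials-last in chunks for cache-friendly
  partitions.
* Averaging the logarithm of a noisy median-based ratio gives the
  estimator a small Jensen-type offset and a slight proportional
  attenuation of injected effects; both apply equally under the null, are
  inherent to the method, and are not corrected for — the recovery study's
  bias bound is what constrains them in practice.
* Event times are rounded to the nearest sample; epoch windows are
  half-open, so a 10 s epoch is exactly 10 000 samples and the alignment
  sample is never double-counted.
* The PL (phase-locked) stream is the wavelet power of the across-trial
  median voltage — a single pseudo-trial, reported as a point estimate
  without bootstrap (resampling it would mean re-transforming per draw);
  NPL transforms evoked-subtracted trials and resamples normally.

## Scaled study sizes

The validation studies run at desk scale, as the package's own choice of
problem size: recovery uses 100 trials × 20 seeds with 6 channels per
array on two arrays (4–6 analysis electrodes each) and the wavelet grid
restricted to the band under test; the saline null uses 20 seeds × 30
trials (10 per condition) on 5 channels of one array with 500 resamples
per test; the interference study uses 10 seeds × 16 trials per arm.
Rest intervals in these studies are 12 s — the minimum honouring the
−5…+5 s epoch windows — rather than the protocol's 40 s, which only adds
recording time between epochs.

## What passing tests do and do not show

The generator emulates the data's *structure* (sampling, grids, bipolar
controller, saturation and desaturation, trial schedule, 1/f + narrow-band
alpha, band-limited multiplicative after-effects) but not electrode
impedance drift, cardiorespiratory or movement artifact, cross-frequency
coupling, non-stationary alpha peak frequency, or any entrainment
dynamics. Parameter recovery and null calibration on these sessions
validate the *pipeline* — the recovery study measures the estimator's
pooled bias, RMSE and cross-array specificity for band-limited ±0.5 dB
effects at 100 trials, and the calibration study checks that the
resampling tests produce uniform p-values under the null — not the
biological claims; and the interference study
shows the *simulator's* loop behaves as the phase budget predicts, not
that a real brain does. Known limitations: additive-drive coupling only;
no tissue or field model; high-gamma wavelet family is a documented guess;
effects shorter than the wavelet support are systematically attenuated by
construction.
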