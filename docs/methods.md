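# Methods

## Scope and model

`minikin` analyses miniature inhibitory postsynaptic currents (mIPSCs)
mediated by GABA_A receptors, recorded in whole-cell voltage clamp, and the
behavioral nociception readouts that accompany such recordings in
developmental / neurosteroid studies.  Because raw recordings are rarely
deposited, the package pairs the analysis pipeline with a synthetic sweep
generator whose ground truth is known exactly, so every stage can be
validated closed-loop: generate a cohort with a documented mean weighted
decay constant, run the full pipeline, and check that the cohort statistics
recover the generator truth.

### Event waveform

Each mIPSC is modelled as a truncated-exponential rise joined continuously
at the peak to an exact biexponential decay:

    y(t) = A * (1 - exp(-t/tau_rise)) / (1 - e^-5),          0 <= t < t_p
    y(t) = A * [p_f exp(-(t-t_p)/tau_f) + (1-p_f) exp(-(t-t_p)/tau_s)],  t >= t_p

with `t_p = 5 * tau_rise` (snapped to the sampling grid so the sampled
extremum equals `A` exactly).  The amplitude fractions `p_f / (1-p_f)` are
defined *at the peak*, which makes the implied weighted decay constant

    tau_w = p_f * tau_f + (1 - p_f) * tau_s

exactly the quantity an ideal peak-onward biexponential fit recovers.  A
single product form `(1-exp(-t/tau_rise)) * biexponential` was considered
and rejected: its post-peak samples deviate from a pure biexponential for a
few rise time constants and its peak-referenced amplitude fractions differ
from the nominal ones, which introduces a ~3% closed-loop tau_w bias and
breaks the exactness of the single-exponential limit.  The piecewise form
has a slope discontinuity at the peak, which is visually similar to real
minis and irrelevant to the decay analysis.

With the default `tau_rise = 0.3 ms` the 10-90% rise time is
`2.14 * tau_rise ~= 0.64 ms`, comfortably inside the 1 ms inclusion bound.

### Generator defaults (and what is, and is not, documented data)

Cohort presets pin the ground-truth tau_w (and the across-cell SD and cell
count) to the documented group values.  A printed tau_w is decomposed into
components by a fixed rule chosen once: `p_f = 0.6`,
`tau_f = 0.45 * tau_w`, hence `tau_s = 1.825 * tau_w` (the identity is then
exact and the tau ratio is ~4, comfortably resolvable by the F test).
Per-cell heterogeneity is created by jittering `tau_slow` only, with SD
`cohort_sd / (1 - p_f)`, so the across-cell SD of true tau_w matches the
documented cohort SD (one-knob identifiability).  Treatment arms are
multiplicative tau_w shifts of their control preset, applied
proportionally to both tau components, because treatment effects are
documented as percent of control.

Event frequency, amplitude distribution and noise level are *not*
documented for any cohort; the defaults are package choices held fixed
across all cohorts:

| parameter | default | rationale |
|---|---|---|
| event rate | 1.2 events/s | typical mini frequency; keeps overlap manageable |
| amplitude | -45 pA mean, log-normal, CV 0.4 | one-signed, right-skewed, well above the -5 pA threshold |
| noise SD | 2.0 pA before filtering (~1.4 pA after) | realistic whole-cell noise; SNR ~30 |
| sampling | 10 kHz | >= 4x the 2 kHz filter corner |
| filter | 4-pole Butterworth, 2 kHz, zero phase | acquisition low-pass; zero-phase keeps onsets unshifted; `filter_cutoff=None` disables it for noiseless oracles |
| events per cell | >= 80 injected | leaves >= 50 accepted events after rejections and overlap flagging |

The ob/ob cortical control tau_w (3.5 ms) is a package choice (the
documented fact is only that it is modestly shorter than the 4.0 ms
wild-type control); the percent-of-control targets are ratios and do not
depend on it.

## Detection

Candidates are negative excursions of the baseline-subtracted trace
crossing the -5 pA threshold, located with a peak finder whose prominence
requirement equals the threshold magnitude (this suppresses noise ripples
riding on the slow tails of earlier events while preserving monotonicity of
the candidate count in |threshold|).  Onsets are found by walking back from
the peak along a 0.3 ms-smoothed trace until the excursion returns to
baseline.  Acceptance applies the three printed criteria — amplitude
<= -5 pA, above-baseline duration > 2 ms, 10-90% rise <= 1 ms — plus a
template-correlation artifact guard (correlation >= 0.5 against a canonical
synaptic shape with the event's own T70-implied tau) standing in for the
manual inspection step, which cannot be reproduced algorithmically.
"Duration" is measured from onset until the excursion first returns to
within one noise SD of baseline.

Events with another substantial candidate (one passing the amplitude
criterion) within 250 ms before or 150 ms after their onset are flagged
`overlapped`: they count toward the >= 50-events-per-cell rule but are
excluded from mean-event construction.  The asymmetric window is
deliberate: a *preceding* event's slow tail decays inside the measurement
window and, after local-offset subtraction, masquerades as extra fast decay
(a ~1% tau_w bias at 100 ms pre-exclusion in noiseless tests); at 250 ms the
residual tail is < 0.1 pA.

### Baseline

The baseline is the centred 0.5 s rolling mean of 2.5 ms block means, with
event-occupied blocks masked (blocks more than 5 block-noise-SD below the
running baseline, mask dilated 250 ms forward to cover decay tails) and
interpolated across; the initial estimate for the masking iteration is a
rolling median.  On an event-free trace no block triggers the mask, so the
estimator reduces to a plain rolling mean and the residual is unbiased —
a robust (median/quantile) final estimator was rejected because its
sampling error alone violates that contract.

## Mean event and decay fitting

Accepted, non-overlapped events are aligned at the interpolated midpoint
(50% point) of their baseline-to-peak rise and resampled onto a common grid
(5 ms before to 150 ms after the midpoint) by linear interpolation, then
averaged point-wise.  The decay is fitted from the peak of the mean event
to the end of the window by trust-region nonlinear least squares
(`scipy.optimize.curve_fit`): monoexponential `A exp(-t/tau)` and
biexponential `A_f exp(-t/tau_f) + A_s exp(-t/tau_s)` with amplitudes
constrained to the sign of the peak, the biexponential from several
documented starting points (log-spaced tau pairs around the mono tau plus a
near-degenerate split of the mono solution, so the null-model improvement
is fully realised); components are reported fast-first.

Model selection uses the extra-sum-of-squares F test on the residual SDs:

    F = [(SSE_mono - SSE_bi) / 2] / [SSE_bi / (n - 4)]

with `SSE = sd^2 * n`; the biexponential is chosen iff p < 0.05.  A
variance-ratio form of the residual-SD comparison would also be defensible;
the extra-sum-of-squares form is the standard nested-model test and is what
the calibration suite validates.  For a mono-selected cell tau_w is the
mono tau (so cohorts mix model classes coherently); for a biexponential
fit,

    tau_w = tau_f * P1 + tau_s * P2,  P1 = A_f / (A_f + A_s),  P2 = 1 - P1.

"Proportion of the decay described by each component" is ambiguous between
amplitude and area fractions; amplitude fractions at the peak are the
dominant convention and the default, with the area-fraction variant
(`P1 = A_f tau_f / (A_f tau_f + A_s tau_s)`) behind the `area_fractions`
flag.

The F-test calibration suite adds white Gaussian noise directly to a
synthetic mono mean event: the extra-sum-of-squares test assumes iid
residuals, and the calibration checks the statistic under its own
assumptions.  Acquisition-filtered noise is correlated at 10 kHz sampling
and would inflate the type-I rate of *any* iid-based selection rule; in the
pipeline this only makes the bi model slightly more likely for cells that
are biexponential anyway.

Cells with fewer than 50 accepted events, failed series-resistance QC
(change > 20% or > 15 MOhm, strict comparisons), or non-converged fits are
excluded from cohort statistics with a logged reason.

## Cohort statistics

Summaries are arithmetic mean +/- sample SD.  Tests: two-sided unpaired /
paired t, one-way ANOVA with Newman-Keuls stepdown post hoc (studentized
range, harmonic-mean n for unequal groups, sub-spans of a non-significant
span declared non-significant untested), and repeated-measures ANOVA via
statsmodels.  Cross-strain "repeated measures" comparisons are modelled as
one-way ANOVA on per-cell values, since cells are not measured repeatedly
across strains.  Treatment effects are `100 * mean(treated) /
mean(control)` with a delta-method SE.  No multiple-testing correction is
applied beyond the post hoc procedure itself.

## Behavior

Tail-flick MPE defaults to the normalized analgesiometry form
`100 * (latency - baseline) / (cutoff - baseline)` clipped to [0, 100]; the
simple form `100 * latency / cutoff` is available because the source
phrasing ("a percentage of 15 seconds") supports it, and reports name the
mode used.  Von Frey frequency is the pooled binomial MLE
`100 * sum(responses) / (10 * n_subjects)`.  The rotarod speed helper uses
a 27 s increment interval (6 to 50 rpm in 11 steps inside the 300 s trial);
the interval is not documented and affects only the helper and simulator
realism, not any statistic.  Censored latencies enter rank tests at the
cutoff value (mid-rank ties).  The behavioral generator draws latencies
from truncated normals censored at the cutoff and von Frey scores from
Binomial(10, p); the wild-type filament probabilities (0.20/0.40/0.60/0.90)
and rotarod parameters are documented values, the tail-flick baselines and
ob/ob sub-threshold filament probabilities are package choices oriented by
the documented directions of effect.

## What the synthetic data do and do not show

The generator reproduces: Poisson event timing, log-normal amplitudes,
biexponential kinetics with across-cell heterogeneity, acquisition
filtering, additive Gaussian noise, and censored/bounded behavioral
outcomes.  It does not reproduce: dendritic filtering gradients (all rise
times are drawn from one kinetic class), amplitude-kinetics correlations,
series-resistance filtering of the synaptic current, multiquantal events,
true artifact waveforms, slow baseline instabilities beyond drift, or
within-subject behavioral correlation across assays.  Passing closed-loop
tests therefore demonstrates the correctness of the *analysis* under the
stated event model, not robustness to every pathology of real recordings.

## Problem sizes and numerics

Closed-loop cohort checks run the documented cell counts (13-32 cells per
cohort, >= 80 injected events per cell, 80 s sweeps at 10 kHz); F-test
calibration uses 1000 null and 200 alternative replicates on 40 ms fit
windows.  Convergence: curve_fit defaults (xtol/ftol ~1e-8) with bounded
parameters; degenerate inputs (zero-SSE biexponential fits, all-tied
Wilcoxon pairs, identical Mann-Whitney samples) are handled with explicit
sentinels (F = +inf, p = 1) rather than exceptions.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; cohort
child seeds are derived with `SeedSequence` keyed by preset name so sibling
cohorts are statistically independent at the same master seed.

## Known limitations

* The detector merges events closer than ~1 ms and can miss a second onset
  riding low on a predecessor's decay; recall on isolated events is >= 0.9
  under default noise but falls for overlapping pairs (by design they are
  excluded from kinetics).
* tau_w recovery carries a small positive bias (~+0.5% under default
  noise) from peak-sample noise selection and finite fit windows; this is
  well inside the 2-SE acceptance bands of the documented cohorts.
* The Newman-Keuls procedure does not control the familywise error rate in
  all configurations (a known property of the procedure, reproduced here
  deliberately for fidelity).
* Percent-of-control dispersion uses the delta method, which understates
  the SE for very small control groups.
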