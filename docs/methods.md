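# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic generator does and does not emulate, and the
known limitations. Units: fluorescence in arbitrary units (a.u.), time in
seconds, rates in events·min⁻¹·ROI⁻¹.

## Generative model of a recording

A bouton's trace is

    F(t) = B(t) · [ F0 + Σ_i  s(t − t_i; A_i, τ) ] + ε(t)

with resting fluorescence `F0` (default 16 400 a.u., so that one quantal
event is a ΔF/F of ~3.8%), white Gaussian noise ε (SD 212 a.u. by default)
and an optional multiplicative photobleach trend
`B(t) = (1 − a_f − a_s) + a_f·e^(−t/τ_f) + a_s·e^(−t/τ_s)`, `B(0) = 1`.
Spontaneous event times are a homogeneous Poisson process (default 0.5
events/min, the 2 mM Ca²⁺ condition); each stimulus time independently
produces an evoked event with a per-synapse probability (default 0.15).
Amplitudes are Gaussian (defaults 623 ± 122 a.u.) truncated at zero by
redraw — negligible at q/σ ≈ 5 but it keeps amplitudes physical. Event
kernels `s` are an instantaneous step followed by a single-exponential decay
(τ = 0.371 s spontaneous, 0.83 s evoked, 0.55 s in Tris mode); in folimycin
mode the step never decays, producing the staircase used to count fusions
irrespective of re-acidification speed. Onsets are continuous in time and
sampled at the true elapsed time since onset, so the sub-frame phase effects
the detector operates under are reproduced.

Dual-channel (pHTomato/GCaMP at 180 ms cycles) recordings couple each
presynaptic event to a postsynaptic event with total probability 0.83; the
frame-offset distribution places 0.83 of its mass on {−1, 0, +1}. These two
numbers make 69% of presynaptic events answered within ±1 frame and 83%
within −1..+5 — the two observed coincidence levels are the study
condition; how the remaining mass spreads over +2..+5 is this package's
choice (a decaying tail). The −1 offsets model fusion midway through an
acquisition cycle, since both channels share one timestamp per cycle.
AP-5 mode suppresses every postsynaptic event and nothing else.

What the generator does **not** emulate: correlated (pink) noise — the
noise autocorrelation of the real recordings is not characterized, so white
noise is assumed; focus drift and lateral motion; vesicle-pool depletion or
release-site structure; amplitude–kinetics correlations. Tests passing on
this generator therefore validate the estimators under the stated
statistical model, not against instrument-specific artifacts.

## Detection criterion

At frame f with baseline the 17 points prior (mean m, sample SD s, floored
at 10⁻⁶ a.u. against noiseless degeneracy): an event requires
`mean(v[f..f+3)) − m > 2s`, a stable preceding 10 s, and ≥ 1 confirmation
point among the 5 frames after the window exceeding the same threshold
(configurable; the confirmation excludes single-point artifacts from which
no decay could be fitted). Stability means: no previously emitted event
onset within 78 frames, and no excursion of the 3-point trailing moving
average beyond 2 noise-SDs from the baseline mean anywhere in that window.
Two implementation choices matter:

- the stability noise scale is a MAD estimate over the 78-frame window
  itself, not the 17-point sample SD — a 17-point SD is noisy enough that
  its low draws would falsely veto 5–8% of clean windows, and a plain SD
  would be inflated by the very excursions being screened;
- the onset is advanced to the first frame of the window whose own value
  (and forward mean) clears the threshold, because the forward mean crosses
  one or two frames before the actual rise for large events. With this
  refinement the measured amplitude of a decaying event equals the true
  amplitude times the analytic attenuation
  `w = (τ/Δt)(1 − e^(−Δt/τ)) · mean_k e^(−kΔt/τ)` (`attenuation_factor`),
  e.g. w = 0.64 for τ = 0.371 s at 8 Hz.

Operating characteristics under white Gaussian noise at the default
parameters (measured in the test suite): ~0.3–0.4 false hits/ROI/min,
symmetric between positive and negative polarity and independent of the
noise scale (the criterion is scale-free); isolated-event recall ~0.85–0.9
for bright events, capped by the stability rule (any threshold-grade noise
hit vetoes the following 10 s) and by the confirmation requirement against
a τ = 0.37 s decay. False hits carry amplitudes just above threshold: among
detections larger than 4× the noise SD of the 3-vs-17 statistic the false
discovery rate is effectively zero. Consumers who need high precision at
spontaneous rates should therefore filter on measured amplitude or tighten
`confirm_points` (at a recall cost).

## Decay kinetics

`fit_decay` fits `A·e^(−t/τ) + c` by Levenberg–Marquardt from the event
peak (the onset frame by default — spontaneous events have no dwell; a peak
search window is available for waveforms with plateaus) to at most 40
frames, stopping before the next event. Initial values: A from the peak
minus baseline, τ = 3 frame intervals, c = baseline. The offset is free, to
tolerate imperfect baseline subtraction. A fit with τ ≤ 0 or no convergence
is flagged, never silently used. At noise/A = 0.2 the estimator's median
recovers τ to within 2–3%; starting the fit at a noisy local maximum
instead of the onset frame biases the median ~7% low, which is why the peak
search is off by default.

Dwell time counts the frames after onset that stay within 2 baseline-SDs of
the onset value; a folimycin staircase therefore yields the remaining trace
duration and an immediately decaying event yields zero.

Populations of fitted τ are summarized by a Beta-distribution MLE on
`[0, scale]` with `scale = 1.05·max(τ)` by default; the reported mean
`scale·α/(α+β)` is the "non-geometric average" decay time. A fixed
`support=(lo, hi)` option exists because the bound-vs-shape parameterization
of such fits is ambiguous in the literature this mirrors; no attempt is
made to privilege either reading.

## Quantal mixture decomposition

Amplitude histograms are modelled as a mixture of at most three Gaussians
with means `q`, `c·q` and exactly `2q`, where c is estimated within
[1.1, 1.6]. A fractional component near 1.3q is expected from pairs of
events separated by ~one frame: the overlap model below shows a 118 ms
delay measures as 1.32q under 3-point sampling, so the c·q component is a
*blurred* double, not a broadened one. Accordingly its SD is a bounded
multiple of σ_q (estimated in [0.9, 1.3]) while the true-double 2q
component has SD exactly 2σ_q. The earlier strictly-proportional
alternative (SD = multiplier × σ_q for every component) was tested and
rejected: it biases the multivesicular weight upward by 0.12–0.18 because
it forces the fractional component to be 1.3× wider than the quantal one,
which such data do not show.

Heavily overlapping mixtures (component separation < 2σ) do not identify
the quantal parameters and the weights jointly from one sample: the
likelihood trades q and σ_q against the weights almost flatly. The model
therefore accepts `calibration=(q, σ_q)` from an independent single-vesicle
measurement and holds the 1q component fixed — the same practice as
classical quantal analysis, where the quantal size is calibrated once and
reused across conditions. With a 1178-event calibration and n ≈ 1200, the
multivesicular weight is recovered with bias < 0.02 and SD ≈ 0.03–0.04
(measured over replicate simulations); unanchored joint estimation remains
available and is adequate for single-component or well-separated data.

Model selection: a D'Agostino–Pearson K2 test on the raw amplitudes at
α = 0.02 *or* a rejected χ² goodness of fit of the single Gaussian (with
the two-component model fitting better) opens the mixture; three components
replace two only when the two-component χ² is rejected and the
three-component fit improves it. χ² uses Freedman–Diaconis bins with open
tails, merged to ≥ 5 expected counts, dof = bins − 1 − parameters. The
normality gate alone has only ~72% power against a 17% admixture at
n = 1200, which is why the χ² evidence is OR-ed in; the false-extension
rate on truly Gaussian data stays at a few percent. Over 50 replicates per
scenario the selected component count matches the generative truth ≥ 80%
of the time (tested).

The multivesicular fraction is the summed weight of components above 1q.
For counting rules ("large events count as two fusions") the boundary is
the posterior-odds crossover between the 1q component and the rest, or
`q + 2σ_q` when no mixture fit is available.

## Two-event overlap model

For two events with amplitudes a₁, a₂ (in quantal folds), onset delay d and
decay τ, sampled at t = 0, Δt, 2Δt from the first onset,

    apparent(d) = mean_k [ a₁·e^(−kΔt/τ) + a₂·e^(−(kΔt−d)/τ)·1(kΔt ≥ d) ].

With τ = 0.371 s, Δt = 0.12 s: apparent(0.118) = 1.3206 (closed form), the
1.3q fractional component. The aligned operator is *piecewise* monotone in
d — it jumps down each time the second onset crosses a sample instant and
rises in between — so its inverse (`find_delay`) is computed per branch in
closed form, e.g. `d = τ·ln[(3T − Σe)/(e₁+e₂)]` for d ≤ Δt with
`e_k = e^(−kΔt/τ)`. Averaging over a uniform sampling phase gives the
smooth form

    apparent(d) = (τ/3Δt)·[a₁(1 − e^(−3Δt/τ)) + a₂(1 − e^(−(3Δt−d)/τ))],

continuous, strictly decreasing, and exactly twice the single-event value
at d = 0; the monotonicity properties are stated (and tested) on this
variant, the worked 1.32 figure on the aligned default. Monte Carlo
populations draw Gaussian amplitude pairs and apply the aligned operator;
their mean converges to the deterministic value at the usual 1/√n rate.

## Dual-channel corrections and coincidence

Photobleach correction fits a double exponential plus constant to the whole
trace (falling back to a single exponential, logged, on non-convergence)
and by default *subtracts* the trend re-anchored at its initial value —
appropriate when the drift is additive background. Because bleaching
actually scales emitted fluorescence, a `mode="divide"` variant rescales by
`B(0)/B(t)` and restores event amplitudes exactly under the generator's
multiplicative bleach; with the default mild bleach (~7% total) the
difference is a few percent of amplitude late in a recording. Around each
event, a local linear baseline over the preceding 15 s (or what exists,
logged) is removed, anchored to preserve the window mean.

Coincidence matching pairs pre- and post-channel events whose onset-frame
offset lies in a window (default ±1), greedily by |offset| with ties toward
the later post frame, one-to-one on both sides. The coupled fraction is
matches / pre-events. Widening the window can only add matches.

## Per-synapse statistics

Events within ±1 s (closed interval) of the nearest stimulus are evoked,
everything else spontaneous; with stimuli ≥ 15 s apart the windows cannot
overlap. The evoked fusion probability counts at most one success per
stimulus. The multivesicular-adjusted spontaneous rate counts events above
the quantal boundary as two fusions. Across synapses, spontaneous rate vs
evoked probability is summarized by Pearson R² (with p), Spearman r (with
p) and the regression slope with its test against zero. The no-correlation
property — independently generated per-synapse rates (Gamma around 0.5/min)
and probabilities (Beta around 0.15) give R² < 0.1 in ≥ 90% of runs — is
verified at the event-count level (Poisson spontaneous counts, binomial
stimulus successes over a 10-min, 20-stimulus design), which is the stage
at which the correlation analysis operates.

## Problem sizes and reproducibility

The test suite and the acceptance script use desk-scale problems: 10-minute
traces at 8 Hz (5 000 frames), 1 100–1 200-event amplitude samples, 500
decay fits, 2 000-pair overlap populations, 50-replicate selection and
null-correlation loops. All stochastic paths take explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
traces and ground truth bit-for-bit.

## Known limitations

- Detection recall/precision at the default 2-SD criterion is intrinsically
  limited on white Gaussian noise (see Detection); the package reports what
  the criterion does rather than improving on it with e.g. matched filters.
- Unanchored mixture weights for overlapping components carry large
  variance; anchor the quantal parameters whenever a calibration exists.
- The Beta decay-time fit fixes the support rather than estimating it;
  estimates of α, β are conditional on that choice.
- `extract_rois` averages square ROIs only (odd sides centered, even sides
  biased toward lower indices; partial ROIs clipped at image borders); no
  registration, background subtraction, or ROI auto-detection.
- The 3-point sampling operator is hard-wired to three samples (the
  moving-average width of the analysis chain); other widths would need the
  closed forms re-derived.
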