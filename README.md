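# svquant

Optical quantal analysis of single synaptic vesicle fusion events from
fluorescence time series.

pH-sensitive probes (vGlut1-pHluorin, SypHTomato) targeted to the synaptic
vesicle lumen report single fusion events as small, fast fluorescence
transients: fusion exposes the probe to neutral pH (a step increase of one
quantal amplitude *q*), and re-acidification after endocytosis quenches it (a
single-exponential decay with time constant τ). `svquant` implements the
complete analysis chain for such recordings:

- **Transient detection** with the moving-average criterion: an event is a
  frame where the mean of 3 points exceeds the mean of the 17 points prior
  by more than 2 of their standard deviations, on a recording that was
  stable for 78 frames (~10 s), with at least one later point re-crossing
  the threshold. The negated criterion estimates the false-hit rate.
- **Decay kinetics**: per-event Levenberg–Marquardt fits of
  `A·exp(−t/τ) + c`, dwell times, onset-aligned average waveforms, and
  Beta-distribution summaries of decay-time populations (the distribution
  mean is the "non-geometric average" decay time).
- **Quantal mixture decomposition** (`QuantalMixtureModel` → `fit()` →
  `QuantalMixtureResults`): amplitude histograms decomposed into Gaussian
  components at *q*, *c·q* (c estimated in [1.1, 1.6]) and exactly *2q*,
  with the 1q component optionally anchored from an independent
  single-vesicle calibration. The summed weight above 1q is the
  multivesicular fraction.
- **Two-event overlap model**: the apparent amplitude of two quantal events
  separated by a short onset delay under 3-point sampling — with τ = 371 ms
  and 120 ms frames, a 118 ms delay produces an apparent amplitude of
  1.32 q, accounting for fractional (≈1.3q) histogram components — plus the
  inverse delay search and a Monte Carlo population version.
- **Dual-channel coincidence**: double-exponential photobleach correction,
  local linear baseline correction, and frame-window matching of
  presynaptic (pHTomato) events to postsynaptic GCaMP Ca²⁺ responses.
- **Per-synapse statistics**: spontaneous rates (with the large-event =
  two-vesicle counting rule), evoked fusion probability per stimulus, and
  the spontaneous-vs-evoked correlation across synapses.
- **Synthetic data**: a ground-truth-labelled generator for every supported
  condition (Poisson spontaneous events, truncated-Gaussian quantal
  amplitudes, exponential decays, folimycin staircase mode, Tris
  slowed-decay mode, photobleaching, stimulus-locked evoked events, and
  coupled two-channel recordings).

## Worked example

```python
import numpy as np
import svquant as sq

# ten-minute recordings of 20 boutons, bright events (10x the noise SD)
cfg = sq.TraceSimConfig(duration=600, spont_rate=0.5, amp_mean=2120,
                        amp_sd=200, noise_sd=212, n_rois=20, seed=42)
traces, truth = sq.simulate_trace(cfg)

events = [e for tr in traces for e in sq.detect_events(tr)]
stat_sd = 212 * (1/3 + 1/17) ** 0.5          # noise SD of the 3-vs-17 statistic
bright = [e for e in events if e.amplitude >= 4 * stat_sd]
by = {tr.roi_id: tr for tr in traces}
taus = [f.tau for e in bright
        if (f := sq.fit_decay(by[e.roi_id], e)).converged and f.tau < 5]
print(len(events), len(bright), len(truth.events))   # 142 74 105
print(round(float(np.median(taus)), 3))              # 0.378
print(round(sq.apparent_amplitude(0.118, 0.371, 0.12), 4))  # 1.3206
```

The detector reports 142 hits: 74 are large (≥ 4× the noise statistic's SD,
essentially all true events) and the remainder are threshold-grade
crossings, consistent with the ~0.3 hits/ROI/min that the same criterion
produces on pure Gaussian noise (measure it with `detect_negative`). The
median fitted decay constant of the bright events, 0.378 s, recovers the
generative τ = 0.371 s. The last line is the overlap model's worked
example: two unit events 118 ms apart, sampled every 120 ms, measure as
1.32 × a single quantal amplitude.

Decomposing an amplitude population that contains 17% near-coincident
double events:

```python
rng = np.random.default_rng(1)
counts = rng.multinomial(1200, (0.83, 0.17))
amps = np.concatenate([rng.normal(623, 122, counts[0]),
                       rng.normal(834, 111, counts[1])])
cal = rng.normal(623, 122, 1178)             # independent 1q calibration
res = sq.fit_quantal_mixture(amps, calibration=(cal.mean(), cal.std(ddof=1)))
print(res.summary())
```

```
Constrained quantal Gaussian mixture
  n events          1200
  components        2
  q (1q mean)       626.7 a.u.
  sigma_q           123.9 a.u.
  c multiplier      1.373 (bounds applied)
  comp 1: mean    626.7  sd   123.9  weight 0.888
  comp 2: mean    860.6  sd   111.5  weight 0.112
  multivesicular    0.112
  chi2 GOF          15.15 (dof=19, p=0.713)
  normality K2 p    0.0013
```

The selector rejects a single Gaussian (normality p = 0.0013), the second
component lands at 1.37 q, and the multivesicular weight estimate is 0.11
(true 0.17; the single-dataset standard error of this weight is ≈ 0.04 at
n = 1200).

A command-line interface mirrors the library:
`svquant simulate | detect | kinetics | quantal | overlap | coincide | correlate`
(see `svquant --help`).

## Layout

```
src/svquant/
  simulate.py   synthetic traces + ground truth
  io.py         CSV trace/event tables, TIFF ROI extraction
  detect.py     transient detection criterion
  kinetics.py   decay fits, dwell times, event averaging
  quantal.py    mixture/noise/Beta models (Model -> fit() -> Results)
  overlap.py    two-event overlap (multivesicular delay) model
  dual.py       bleach/baseline correction, coincidence matching
  synapse.py    classification, rates, correlation
  cli.py        command-line entry points
docs/methods.md  model assumptions, parameter choices, limitations
```
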