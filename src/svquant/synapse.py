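"""Per-synapse spontaneous/evoked classification, rates and correlation.

An event is evoked when its onset lies within one second of the nearest
stimulus (stimuli are delivered 15-30 s apart, so windows never overlap);
everything else is spontaneous.  Per-ROI summaries report the spontaneous
rate (events/min), a multivesicular-adjusted rate in which events larger than
the single-quantal boundary count as two vesicle fusions, and the evoked
fusion probability (fraction of stimuli answered by at least one evoked
event).  Across synapses, the spontaneous rate and evoked probability are
compared by Pearson/Spearman correlation and a regression slope with its
test against zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .detect import DetectedEvent
from .quantal import QuantalMixtureResults

__all__ = [
    "SynapseSummary",
    "CorrelationResult",
    "classify_events",
    "multivesicular_boundary",
    "synapse_summary",
    "correlate_rates",
]


@dataclass
class SynapseSummary:
    """Event statistics of one ROI (bouton)."""

    roi_id: str
    spont_rate: float                 # events / min
    spont_rate_mv_adjusted: float     # events / min, large events counted twice
    evoked_prob: float | None         # fraction of stimuli with >= 1 evoked event
    n_spont: int
    n_evoked: int
    n_stimuli: int


@dataclass
class CorrelationResult:
    """Spontaneous-rate vs evoked-probability correlation across synapses."""

    pearson_r2: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    slope: float            # (events/min) per unit probability
    intercept: float
    slope_p: float          # test of slope = 0
    n: int

    def summary(self) -> str:
        return (
            "Spontaneous rate vs evoked probability\n"
            f"  n synapses  {self.n}\n"
            f"  slope       {self.slope:.3f} (p[slope=0] = {self.slope_p:.4f})\n"
            f"  Pearson R^2 {self.pearson_r2:.4f} (p = {self.pearson_p:.4f})\n"
            f"  Spearman r  {self.spearman_r:.4f} (p = {self.spearman_p:.4f})"
        )


def classify_events(
    events: Sequence[DetectedEvent],
    stim_times: Sequence[float],
    window: float = 1.0,
) -> list[tuple[DetectedEvent, str]]:
    """Label each event ``"evoked"`` or ``"spontaneous"``.

    Evoked iff the onset lies within ``window`` seconds (closed interval) of
    the nearest stimulus.  Labels are exhaustive and exclusive.
    """
    st = np.sort(np.asarray(stim_times, dtype=float))
    out = []
    for e in events:
        if st.size:
            i = np.searchsorted(st, e.onset_time)
            nearest = min(
                (abs(e.onset_time - st[j]) for j in (i - 1, i) if 0 <= j < st.size)
            )
            label = "evoked" if nearest <= window else "spontaneous"
        else:
            label = "spontaneous"
        out.append((e, label))
    return out


def multivesicular_boundary(mixture: QuantalMixtureResults | None, q: float, sigma_q: float) -> float:
    """Amplitude above which an event is counted as two vesicle fusions.

    Without a mixture fit the boundary is ``q + 2*sigma_q``; with one it is
    the posterior-odds crossover between the single-quantal component and the
    multivesicular components.
    """
    if mixture is None or mixture.n_components == 1:
        return q + 2.0 * sigma_q
    w, means, sds = mixture.weights, mixture.means, mixture.sds

    def odds(a):
        p1 = w[0] * stats.norm.pdf(a, means[0], sds[0])
        pm = sum(wk * stats.norm.pdf(a, mk, sk) for wk, mk, sk in zip(w[1:], means[1:], sds[1:]))
        return p1 - pm

    lo, hi = means[0], means[-1]
    if odds(lo) <= 0:  # degenerate overlap; fall back
        return mixture.q + 2.0 * mixture.sigma_q
    while odds(hi) > 0 and hi < means[-1] * 3:
        hi *= 1.2
    return float(optimize.brentq(odds, lo, hi))


def synapse_summary(
    labeled_events: Sequence[tuple[DetectedEvent, str]],
    duration: float,
    n_stimuli: int,
    mixture: QuantalMixtureResults | None = None,
    q: float = 623.0,
    sigma_q: float = 122.0,
    roi_id: str | None = None,
    stim_times: Sequence[float] | None = None,
    window: float = 1.0,
) -> SynapseSummary:
    """Summarize one ROI's labeled events over ``duration`` seconds.

    The multivesicular-adjusted rate counts an event as two fusions when its
    amplitude exceeds :func:`multivesicular_boundary`.  The evoked fusion
    probability counts at most one success per stimulus (pass ``stim_times``
    so repeated events after one stimulus collapse into one success); with no
    stimuli it is reported as missing (``None``).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    events = [e for e, _ in labeled_events]
    if roi_id is None:
        roi_id = events[0].roi_id if events else "roi"
    boundary = multivesicular_boundary(mixture, q, sigma_q)
    spont = [e for e, lab in labeled_events if lab == "spontaneous"]
    evoked = [e for e, lab in labeled_events if lab == "evoked"]
    n_spont = len(spont)
    n_adj = sum(2 if e.amplitude > boundary else 1 for e in spont)
    minutes = duration / 60.0
    if n_stimuli > 0:
        if stim_times is not None:
            st = np.asarray(stim_times, dtype=float)
            answered = {
                int(np.argmin(np.abs(st - e.onset_time)))
                for e in evoked
                if np.min(np.abs(st - e.onset_time)) <= window
            }
            evoked_prob = len(answered) / n_stimuli
        else:
            evoked_prob = min(len(evoked), n_stimuli) / n_stimuli
    else:
        evoked_prob = None
    return SynapseSummary(
        roi_id=roi_id,
        spont_rate=n_spont / minutes,
        spont_rate_mv_adjusted=n_adj / minutes,
        evoked_prob=evoked_prob,
        n_spont=n_spont,
        n_evoked=len(evoked),
        n_stimuli=n_stimuli,
    )


def correlate_rates(summaries: Sequence[SynapseSummary]) -> CorrelationResult:
    """Correlate spontaneous rate with evoked probability across synapses."""
    pts = [
        (s.evoked_prob, s.spont_rate)
        for s in summaries
        if s.evoked_prob is not None
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 synapses with defined evoked probability")
    x = np.array([p for p, _ in pts])
    y = np.array([r for _, r in pts])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in rates or probabilities")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    reg = stats.linregress(x, y)
    return CorrelationResult(
        pearson_r2=float(pr.statistic**2),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        slope_p=float(reg.pvalue),
        n=x.size,
    )
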