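"""Dual-channel (pHTomato pre / GCaMP post) corrections and coincidence.

The red channel bleaches appreciably over long recordings; the full trace is
fitted with a double-exponential decay and the fitted trend subtracted (the
baseline is re-anchored at its initial value).  Around each detected event
the local baseline is additionally detrended with the least-squares line of
the preceding 15 s.  Presynaptic fusion events are then validated by
coincidence with postsynaptic Ca2+ events: a pre event counts as coupled when
an unmatched post event's onset lies within a frame window of its own onset
(both channels share one timestamp per acquisition cycle, so an event landing
halfway through a cycle can legitimately appear at -1 frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .detect import DetectedEvent
from .io import FluorescenceTrace

__all__ = [
    "CoincidenceResult",
    "correct_photobleach",
    "local_baseline_correct",
    "match_events",
]

log = logging.getLogger(__name__)


@dataclass
class CoincidenceResult:
    """Outcome of pre/post event matching within a frame window."""

    matches: list[tuple[DetectedEvent, DetectedEvent, int]]  # (pre, post, offset)
    fraction_in_window: float
    window: tuple[int, int]
    n_pre: int
    n_post: int


def _double_exp(t, a1, t1, a2, t2, c):
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + c


def _single_exp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def correct_photobleach(trace: FluorescenceTrace, mode: str = "subtract") -> FluorescenceTrace:
    """Remove slow photobleaching with a double-exponential trend fit.

    Fits ``B(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) + c`` to the whole trace.
    ``mode="subtract"`` (default) returns ``values - B(t) + B(0)``: the trend
    is flattened while the initial fluorescence level is preserved.
    ``mode="divide"`` returns ``values * B(0)/B(t)``, which restores event
    amplitudes exactly when bleaching scales the emitted fluorescence
    multiplicatively.  If the double exponential does not converge the
    correction falls back to a single exponential (logged); if that also
    fails the trace is returned unchanged (logged).
    """
    if mode not in ("subtract", "divide"):
        raise ValueError("mode must be 'subtract' or 'divide'")
    if trace.n_frames < 50:
        raise ValueError("need at least 50 frames to estimate a bleach trend")
    t = trace.times - trace.t0
    v = trace.values
    span = float(v[: max(trace.n_frames // 20, 5)].mean() - v[-max(trace.n_frames // 20, 5):].mean())
    dur = t[-1] if t[-1] > 0 else 1.0
    p0 = (0.5 * span, dur / 10, 0.5 * span, dur, float(v.min()))
    trend = None
    try:
        popt, _ = curve_fit(
            _double_exp, t, v, p0=p0,
            bounds=([-np.inf, 1e-3, -np.inf, 1e-3, -np.inf], np.inf),
            maxfev=20000,
        )
        trend = _double_exp(t, *popt)
    except (RuntimeError, ValueError):
        log.warning(
            "double-exponential bleach fit failed for %s; falling back to single",
            trace.roi_id,
        )
        try:
            popt, _ = curve_fit(
                _single_exp, t, v, p0=(span, dur / 3, float(v.min())),
                bounds=([-np.inf, 1e-3, -np.inf], np.inf), maxfev=20000,
            )
            trend = _single_exp(t, *popt)
        except (RuntimeError, ValueError):
            log.warning("bleach correction skipped for %s (no fit converged)", trace.roi_id)
            return trace.copy()
    if mode == "divide":
        return trace.copy(values=v * (trend[0] / trend))
    return trace.copy(values=v - trend + trend[0])


def local_baseline_correct(
    trace: FluorescenceTrace, event: DetectedEvent, lookback: float = 15.0
) -> FluorescenceTrace:
    """Remove the local baseline slope around one event.

    Fits a least-squares line to the ``lookback`` seconds before the event
    onset and subtracts it from the onset of that window to the end of the
    trace, anchored so the mean of the corrected lookback window equals the
    mean of the raw one.  With fewer frames than requested available the fit
    uses what exists (logged).
    """
    n_back = int(round(lookback / trace.frame_interval))
    f0 = event.onset_frame
    if f0 < 2:
        raise ValueError("event onset too early for any baseline window")
    if f0 < n_back:
        log.warning(
            "only %d of %d lookback frames available before event at frame %d",
            f0, n_back, f0,
        )
        n_back = f0
    v = trace.values.copy()
    seg = slice(f0 - n_back, f0)
    x = np.arange(n_back, dtype=float)
    slope, intercept = np.polyfit(x, v[seg], 1)
    x_all = np.arange(f0 - n_back, v.size, dtype=float) - (f0 - n_back)
    # subtract the line re-centred at the window mean: window mean is preserved
    v[f0 - n_back :] -= slope * (x_all - x.mean())
    return trace.copy(values=v)


def match_events(
    pre_events: list[DetectedEvent],
    post_events: list[DetectedEvent],
    window: tuple[int, int] = (-1, 1),
) -> CoincidenceResult:
    """Match pre-channel events to post-channel events by onset-frame offset.

    ``offset = post.onset_frame - pre.onset_frame`` must lie in
    ``[window[0], window[1]]``.  Matching is greedy by smallest ``|offset|``
    with ties resolved toward the later post frame (a fusion event midway
    through an acquisition cycle legitimately shows up one frame early in the
    pre channel); each event on either side is used at most once.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window must satisfy lo <= hi")
    candidates = []
    for i, pre in enumerate(pre_events):
        for j, post in enumerate(post_events):
            off = post.onset_frame - pre.onset_frame
            if lo <= off <= hi:
                candidates.append((abs(off), -off, i, j, off))
    candidates.sort()
    used_pre: set[int] = set()
    used_post: set[int] = set()
    matches = []
    for _, _, i, j, off in candidates:
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        matches.append((pre_events[i], post_events[j], off))
    frac = len(matches) / len(pre_events) if pre_events else 0.0
    return CoincidenceResult(matches, frac, (lo, hi), len(pre_events), len(post_events))
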