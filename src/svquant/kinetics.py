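"""Decay kinetics of detected fusion events.

The fluorescence decay after a spontaneous fusion event is dominated by
vesicle re-acidification and is well described by a single exponential,
``A * exp(-(t - t_peak)/tau) + c``, fitted by Levenberg-Marquardt least
squares.  Dwell time — the pause between the fluorescence rise and the onset
of decay — reflects surface residency of the probe and is typically zero for
spontaneous events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .detect import DetectedEvent
from .io import FluorescenceTrace

__all__ = [
    "DecayFit",
    "fit_decay",
    "dwell_time",
    "average_events",
    "attenuation_factor",
]


@dataclass
class DecayFit:
    """Single-exponential decay fit of one event."""

    tau: float          # s
    amplitude: float    # a.u.
    offset: float       # a.u.
    rss: float          # residual sum of squares, a.u.^2
    converged: bool
    n_points: int = 0

    def as_dict(self) -> dict:
        return {
            "tau": self.tau,
            "amplitude": self.amplitude,
            "offset": self.offset,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }


def _exp_decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_decay(
    trace: FluorescenceTrace,
    event: DetectedEvent,
    window: int = 40,
    next_onset: int | None = None,
    peak_search: int = 1,
) -> DecayFit:
    """Fit ``A*exp(-(t-t_peak)/tau) + c`` to the post-peak segment of one event.

    Spontaneous events decay immediately, so by default the onset frame is
    the peak; pass ``peak_search > 1`` to search the following frames for a
    later maximum (waveforms with dwell).  The fitted segment runs from the
    peak to ``min(onset + window, next_onset)``.  Fewer than 4 usable frames raises; a failed or
    nonphysical (tau <= 0) fit returns ``converged=False``.
    """
    v = np.asarray(trace.values, float)
    f0 = event.onset_frame
    peak = f0 + int(np.argmax(v[f0 : min(f0 + peak_search, v.size)]))
    end = min(f0 + window, v.size)
    if next_onset is not None:
        end = min(end, next_onset)
    seg = v[peak:end]
    if seg.size < 4:
        raise ValueError(f"only {seg.size} frames after peak; need >= 4")
    t = np.arange(seg.size) * trace.frame_interval
    base = event.baseline_mean
    p0 = (max(v[peak] - base, 1e-9), 3 * trace.frame_interval, base)
    try:
        # LM explores tau near zero where exp overflows harmlessly
        with np.errstate(over="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_exp_decay, t, seg, p0=p0, method="lm", maxfev=5000)
    except RuntimeError:
        return DecayFit(float("nan"), float("nan"), float("nan"), float("inf"), False, seg.size)
    a, tau, c = map(float, popt)
    rss = float(np.sum((seg - _exp_decay(t, *popt)) ** 2))
    ok = np.isfinite(tau) and tau > 0
    return DecayFit(tau if ok else float("nan"), a, c, rss, ok, seg.size)


def dwell_time(
    trace: FluorescenceTrace, event: DetectedEvent, k_sd: float = 2.0
) -> float:
    """Seconds the fluorescence stays at its peak before decay begins.

    Counts consecutive frames after the onset frame whose value remains
    within ``k_sd * baseline_sd`` of the peak value; zero when the decay
    starts at the very next frame.  A non-decaying (folimycin) staircase
    yields the remaining trace duration.
    """
    v = np.asarray(trace.values, float)
    f0 = event.onset_frame
    peak = v[f0]
    tol = k_sd * event.baseline_sd
    count = 0
    for j in range(f0 + 1, v.size):
        if abs(v[j] - peak) <= tol:
            count += 1
        else:
            break
    return count * trace.frame_interval


def average_events(
    traces: Sequence[FluorescenceTrace],
    events: Sequence[DetectedEvent],
    pre_frames: int = 8,
    post_frames: int = 17,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Onset-aligned mean waveform across events, with per-frame SEM.

    Each event's segment is baseline-subtracted (mean of its ``pre_frames``
    window) before averaging; events whose window leaves the trace are
    skipped.  Returns ``(t, mean, sem)`` with ``t = 0`` at the onset frame.
    """
    if not events:
        raise ValueError("no events to average")
    by_roi = {t.roi_id: t for t in traces}
    segs = []
    dt = None
    for e in events:
        tr = by_roi.get(e.roi_id)
        if tr is None:
            continue
        lo, hi = e.onset_frame - pre_frames, e.onset_frame + post_frames
        if lo < 0 or hi > tr.n_frames:
            continue
        seg = tr.values[lo:hi].astype(float)
        seg = seg - seg[:pre_frames].mean() if pre_frames else seg - e.baseline_mean
        segs.append(seg)
        dt = tr.frame_interval
    if not segs:
        raise ValueError("no event window fits inside its trace")
    arr = np.vstack(segs)
    mean = arr.mean(axis=0)
    sem = (
        arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        if arr.shape[0] > 1
        else np.zeros_like(mean)
    )
    t = (np.arange(-pre_frames, post_frames)) * dt
    return t, mean, sem


def attenuation_factor(
    tau: float, frame_interval: float, avg_len: int = 3, phase: str = "uniform"
) -> float:
    """Expected attenuation of a decaying event's amplitude by the moving average.

    A transient of unit amplitude sampled at its onset frame and averaged over
    ``avg_len`` frames measures ``mean_k exp(-k*dt/tau)`` of its true height;
    with event onsets uniformly distributed within a frame (``phase =
    'uniform'``) the mean sub-frame lag contributes a further factor
    ``(tau/dt)*(1 - exp(-dt/tau))``.
    """
    if tau <= 0 or frame_interval <= 0:
        raise ValueError("tau and frame_interval must be positive")
    k = np.arange(avg_len)
    w = float(np.mean(np.exp(-k * frame_interval / tau)))
    if phase == "uniform":
        w *= tau / frame_interval * (1.0 - np.exp(-frame_interval / tau))
    elif phase != "aligned":
        raise ValueError("phase must be 'uniform' or 'aligned'")
    return w
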