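"""Detection of fluorescence transients from single-vesicle fusion events.

An event is called at the first frame ``f`` where the average of ``avg_len``
(default 3) points, minus the mean of the ``baseline_len`` (default 17, ~2.1 s
at 8 Hz) points immediately prior, exceeds ``k_sd`` (default 2) times the
standard deviation of those baseline points — provided the recording was
stable for ``stability_len`` (default 78, ~10 s) frames before the increase,
and at least ``confirm_points`` additional points after the initial window
also exceed the same threshold (excluding single-point artifacts from which
no decay time could be measured).

"Stable" is implemented as: no previously emitted event onset within the
preceding ``stability_len`` frames, and no excursion of the 3-point trailing
moving average beyond ``k_sd`` noise SDs (either direction) from the
baseline mean anywhere in that window.  The moving average — not the raw
points — carries the stability check because single raw points routinely
cross 2 SD in Gaussian noise, and the noise scale of the stability window is
estimated robustly (MAD) so that the excursions being screened for do not
inflate their own threshold.

The same criterion applied to the negated trace (``detect_negative``)
estimates the false-hit rate: symmetric noise should produce negative-going
"events" at the same rate as false positive ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import FluorescenceTrace

__all__ = [
    "DetectionParams",
    "DetectedEvent",
    "detect_events",
    "detect_negative",
    "noise_amplitudes",
]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the transient-detection criterion (defaults: 8 Hz imaging)."""

    avg_len: int = 3           # frames averaged for the event statistic
    baseline_len: int = 17     # frames of baseline prior (~2.1 s)
    k_sd: float = 2.0          # threshold in baseline SDs
    stability_len: int = 78    # required stable frames before onset (~10 s)
    confirm_points: int = 1    # points after the window that must re-cross threshold
    confirm_lookahead: int = 5 # frames searched for confirmation points
    polarity: str = "positive"
    min_baseline_sd: float = 1e-6  # floor against zero-SD degeneracy

    def __post_init__(self) -> None:
        if self.avg_len < 1:
            raise ValueError("avg_len must be >= 1")
        if self.baseline_len < 2:
            raise ValueError("baseline_len must be >= 2")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if self.stability_len < self.baseline_len:
            raise ValueError("stability_len must be >= baseline_len")
        if self.confirm_points < 0 or self.confirm_lookahead < self.confirm_points:
            raise ValueError("need 0 <= confirm_points <= confirm_lookahead")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


@dataclass
class DetectedEvent:
    """One detected transient."""

    roi_id: str
    onset_frame: int
    onset_time: float       # s
    amplitude: float        # a.u., above baseline (magnitude for negative events)
    dff: float              # amplitude / baseline fluorescence
    baseline_mean: float    # a.u.
    baseline_sd: float      # a.u.
    polarity: int = 1

    def as_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "onset_frame": self.onset_frame,
            "onset_time": self.onset_time,
            "amplitude": self.amplitude,
            "dff": self.dff,
            "baseline_mean": self.baseline_mean,
            "baseline_sd": self.baseline_sd,
            "polarity": self.polarity,
        }


def _trailing_smooth(v: np.ndarray, width: int) -> np.ndarray:
    """Trailing moving average; shorter partial windows at the start."""
    c = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(v.size)
    lo = np.maximum(idx - width + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def detect_events(
    trace: FluorescenceTrace, params: DetectionParams | None = None
) -> list[DetectedEvent]:
    """Apply the transient-detection criterion to one trace, left to right.

    Events are greedy and non-overlapping: a new onset may be considered only
    after the confirmation window of the previous event, and never within
    ``stability_len`` frames of it.
    """
    p = params or DetectionParams()
    v = np.asarray(trace.values, dtype=float)
    negate = p.polarity == "negative"
    if negate:
        v = -v
    n = v.size
    if n <= p.stability_len + p.avg_len:
        raise ValueError(
            f"trace {trace.roi_id!r} too short ({n} frames) for "
            f"stability_len={p.stability_len} + avg_len={p.avg_len}"
        )

    # rolling baseline stats over the baseline_len frames before each f
    base_win = sliding_window_view(v, p.baseline_len)       # [i] = v[i : i+bl]
    bmean_at = base_win.mean(axis=1)                        # baseline ending at f: index f - bl
    bsd_at = base_win.std(axis=1, ddof=1)
    # forward event statistic windows
    ev_win = sliding_window_view(v, p.avg_len)              # [f] = v[f : f+avg]
    fmean = ev_win.mean(axis=1)
    # smoothed trace for the stability excursion check
    smooth = _trailing_smooth(v, p.avg_len)
    # extrema of the smoothed trace over the stability window before f
    stab_win = sliding_window_view(smooth, p.stability_len) # [i] = smooth[i : i+sl]
    smax = stab_win.max(axis=1)
    smin = stab_win.min(axis=1)
    # robust noise scale of each stability window (MAD): a 17-point sample SD
    # is too noisy to gate 78 frames, and a raw SD is inflated by the very
    # excursions the check must catch
    raw_win = sliding_window_view(v, p.stability_len)
    med = np.median(raw_win, axis=1)
    stab_sd = 1.4826 * np.median(np.abs(raw_win - med[:, None]), axis=1)

    events: list[DetectedEvent] = []
    last_onset = -10**9
    f = p.stability_len
    f_max = n - p.avg_len
    while f <= f_max:
        bmean = bmean_at[f - p.baseline_len]
        bsd = max(bsd_at[f - p.baseline_len], p.min_baseline_sd)
        thresh = p.k_sd * bsd
        stat = fmean[f] - bmean
        if stat > thresh:
            stab_thresh = p.k_sd * max(stab_sd[f - p.stability_len], p.min_baseline_sd)
            stable = (
                f - last_onset >= p.stability_len
                and smax[f - p.stability_len] - bmean <= stab_thresh
                and bmean - smin[f - p.stability_len] <= stab_thresh
            )
            if stable:
                # the forward mean can cross threshold one or two frames
                # before the actual rise; anchor the onset at the first frame
                # that itself clears the threshold (with its window mean)
                f_star = f
                for g in range(f, min(f + p.avg_len, f_max + 1)):
                    if v[g] - bmean > thresh and fmean[g] - bmean > thresh:
                        f_star = g
                        break
                stat_star = fmean[f_star] - bmean
                j0 = f_star + p.avg_len
                j1 = min(j0 + p.confirm_lookahead, n)
                n_confirm = int(np.count_nonzero(v[j0:j1] - bmean > thresh))
                if n_confirm >= p.confirm_points:
                    sign = -1 if negate else 1
                    raw_bmean = -bmean if negate else bmean
                    dff = stat_star / abs(raw_bmean) if raw_bmean != 0 else float("nan")
                    events.append(
                        DetectedEvent(
                            roi_id=trace.roi_id,
                            onset_frame=f_star,
                            onset_time=trace.t0 + f_star * trace.frame_interval,
                            amplitude=float(stat_star),
                            dff=float(dff),
                            baseline_mean=float(raw_bmean),
                            baseline_sd=float(bsd),
                            polarity=sign,
                        )
                    )
                    last_onset = f_star
                    f = f_star + p.avg_len + p.confirm_lookahead
                    continue
        f += 1
    return events


def detect_negative(
    trace: FluorescenceTrace, params: DetectionParams | None = None
) -> list[DetectedEvent]:
    """Apply the identical criterion to the negated trace (false-hit control).

    Returned events carry the excursion magnitude as ``amplitude`` with
    ``polarity = -1``.
    """
    p = params or DetectionParams()
    if p.polarity == "negative":
        raise ValueError("params.polarity is already 'negative'; call detect_events")
    neg = DetectionParams(
        avg_len=p.avg_len,
        baseline_len=p.baseline_len,
        k_sd=p.k_sd,
        stability_len=p.stability_len,
        confirm_points=p.confirm_points,
        confirm_lookahead=p.confirm_lookahead,
        polarity="negative",
        min_baseline_sd=p.min_baseline_sd,
    )
    return detect_events(trace, neg)


def noise_amplitudes(
    trace: FluorescenceTrace,
    params: DetectionParams | None = None,
    n: int = 1000,
    seed: int | None = None,
    events: Sequence[DetectedEvent] | None = None,
) -> np.ndarray:
    """Noise distribution of the detection statistic at random event-free times.

    Returns ``n`` values of mean(avg_len points) - mean(baseline_len prior
    points) at uniformly random positions whose measurement frames do not
    overlap any detected-event window.  Pass precomputed ``events`` to skip
    re-detection.
    """
    p = params or DetectionParams()
    v = np.asarray(trace.values, dtype=float)
    if events is None:
        events = detect_events(trace, p)
    guard = p.avg_len + p.confirm_lookahead
    ok = np.zeros(v.size, dtype=bool)
    ok[p.baseline_len : v.size - p.avg_len + 1] = True
    for e in events:
        lo = max(e.onset_frame - p.avg_len - p.baseline_len, 0)
        hi = min(e.onset_frame + guard + p.baseline_len, v.size)
        ok[lo:hi] = False
    eligible = np.flatnonzero(ok)
    if n > eligible.size:
        raise ValueError(
            f"requested {n} noise windows but only {eligible.size} event-free positions"
        )
    rng = np.random.default_rng(seed)
    pos = rng.choice(eligible, size=n, replace=False)
    out = np.empty(n)
    for i, f in enumerate(pos):
        out[i] = v[f : f + p.avg_len].mean() - v[f - p.baseline_len : f].mean()
    return out
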