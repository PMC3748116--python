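"""Peristaltic stride detection and crawling-run segmentation.

Larval crawling makes the centroid speed oscillate: each peristaltic stride
ends with the anterior being propelled forward, producing one local maximum
in the speed trace.  Strides are therefore speed peaks; a peak is *good*
when its amplitude exceeds a fixed floor (0.6 mm/s) and at least 3/10 of
the mean peak amplitude of the whole trace.  A crawling run is a chain of
at least three adjacent good peaks; the chain breaks when two adjacent good
peaks are more than 2 s apart or when a roll or head cast starts between
them.  Stride frequency of a run comes from a Lomb-Scargle periodogram of
the run's speed segment, which is valid for the unevenly sampled series
that frame drops produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lombscargle

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedPeak",
    "RunRecord",
    "RunConfig",
    "find_speed_peaks",
    "classify_good_peaks",
    "assemble_runs",
    "stride_frequency",
]


@dataclass
class SpeedPeak:
    """One local maximum of the speed trace (one candidate stride)."""

    index: int
    t_peak: float
    amplitude: float
    left_bound: float   # time of the nearest local minimum to the left
    right_bound: float  # time of the nearest local minimum to the right
    is_good: bool = False


@dataclass
class RunRecord:
    """A crawling run: a chain of at least ``min_peaks`` good strides."""

    larva_id: str
    t_start: float
    t_end: float
    n_strides: int
    mean_max_stride_speed: float  # mean amplitude of the member good peaks
    stride_frequency: float       # Lomb-Scargle argmax, Hz
    terminated_by: str = "track_end"  # gap | roll | cast | hunch | track_end
    frequency_reliable: bool = True


@dataclass
class RunConfig:
    """Run-detection parameters.

    ``abs_floor`` and ``rel_fraction`` define good peaks, ``min_peaks`` and
    ``max_gap`` define runs.  The frequency grid spans ``f_min``..``f_max``
    Hz with a resolution of ``1 / (oversampling * segment duration)``,
    bracketing larval stride rates well below the 7.5 Hz Nyquist limit of
    15 fps tracking.
    """

    abs_floor: float = 0.6       # mm/s
    rel_fraction: float = 0.3    # of mean peak amplitude over the full trace
    min_peaks: int = 3
    max_gap: float = 2.0         # s, peak-position to peak-position
    f_min: float = 0.2           # Hz
    f_max: float = 5.0           # Hz
    oversampling: int = 4

    def __post_init__(self) -> None:
        if self.abs_floor <= 0 or not (0 < self.rel_fraction < 1):
            raise ValueError("abs_floor must be > 0 and 0 < rel_fraction < 1")
        if self.min_peaks < 2:
            raise ValueError("min_peaks must be >= 2")


def find_speed_peaks(times: np.ndarray, speed: np.ndarray) -> list[SpeedPeak]:
    """All strict local maxima of the speed trace, with flanking minima.

    Plateaus (runs of equal values higher than both neighbours) resolve to
    the plateau midpoint.  Peak boundaries are the nearest local minima on
    each side; track ends count as minima.  NaN samples (undefined speed at
    track edges) are excluded: peaks are searched on the finite span only.
    """
    times = np.asarray(times, dtype=float)
    speed = np.asarray(speed, dtype=float)
    finite = np.flatnonzero(np.isfinite(speed))
    if finite.size < 3:
        return []
    lo, hi = finite[0], finite[-1]
    t = times[lo : hi + 1]
    y = speed[lo : hi + 1]
    y = np.nan_to_num(y, nan=float(np.nanmin(y)))  # interior NaNs, if any
    n = len(y)

    peaks: list[SpeedPeak] = []
    i = 1
    while i < n - 1:
        if y[i] <= y[i - 1]:
            i += 1
            continue
        # rising into i; find the plateau [i, j] of equal values
        j = i
        while j < n - 1 and y[j + 1] == y[i]:
            j += 1
        if j < n - 1 and y[j + 1] < y[i]:
            mid = (i + j) // 2
            # walk outward to the flanking minima (plateaus pass through)
            a = i
            while a > 0 and y[a - 1] <= y[a]:
                a -= 1
            b = j
            while b < n - 1 and y[b + 1] <= y[b]:
                b += 1
            peaks.append(
                SpeedPeak(
                    index=lo + mid,
                    t_peak=float(t[mid]),
                    amplitude=float(y[mid]),
                    left_bound=float(t[a]),
                    right_bound=float(t[b]),
                )
            )
        i = j + 1
    return peaks


def classify_good_peaks(
    peaks: Sequence[SpeedPeak], config: RunConfig = RunConfig()
) -> list[SpeedPeak]:
    """Flag good peaks: amplitude above the floor AND >= rel_fraction of the
    mean amplitude over *all* detected peaks of the trace."""
    peaks = list(peaks)
    if not peaks:
        return []
    mean_amp = float(np.mean([p.amplitude for p in peaks]))
    for p in peaks:
        p.is_good = (
            p.amplitude > config.abs_floor
            and p.amplitude >= config.rel_fraction * mean_amp
        )
    return peaks


def stride_frequency(
    times: np.ndarray,
    speed: np.ndarray,
    config: RunConfig = RunConfig(),
) -> tuple[float, bool]:
    """Dominant frequency of a run's speed segment via Lomb-Scargle.

    Returns ``(frequency_hz, reliable)``.  The estimate is flagged
    unreliable when the segment is shorter than two nominal periods at
    ``f_min`` or when no dominant spectral peak stands at least 3x above
    the median periodogram power (e.g. pure noise).
    """
    times = np.asarray(times, dtype=float)
    speed = np.asarray(speed, dtype=float)
    finite = np.isfinite(speed)
    t = times[finite]
    y = speed[finite]
    if len(t) < 4 or t[-1] <= t[0]:
        return float("nan"), False
    span = float(t[-1] - t[0])
    df = 1.0 / (config.oversampling * span)
    freqs = np.arange(config.f_min, config.f_max + df / 2, df)
    power = lombscargle(t - t[0], y - y.mean(), 2 * np.pi * freqs)
    f_hat = float(freqs[int(np.argmax(power))])
    dominant = float(np.max(power)) >= 3.0 * float(np.median(power))
    long_enough = span >= 2.0 / config.f_min
    return f_hat, bool(dominant and long_enough)


def _interrupting_between(
    t_prev: float, t_next: float, interrupting: Sequence
) -> str | None:
    for ev in interrupting:
        if t_prev < ev.t_start < t_next:
            return "cast" if ev.type.startswith("cast") else ev.type
    return None


def assemble_runs(
    larva_id: str,
    times: np.ndarray,
    speed: np.ndarray,
    peaks: Sequence[SpeedPeak],
    config: RunConfig = RunConfig(),
    interrupting_events: Sequence = (),
) -> list[RunRecord]:
    """Chain good peaks into crawling runs and extract run features.

    Good peaks chain while consecutive peak positions are at most
    ``max_gap`` apart and no interrupting event (roll or head cast) starts
    between them; bad peaks in between do not break adjacency.  Chains of
    at least ``min_peaks`` peaks become runs whose boundaries are the left
    bound of the first and the right bound of the last member peak,
    clamped so that no interrupting event interval lies inside a run:
    peaks occurring during an interrupting event are not strides.
    ``interrupting_events`` must offer ``t_start``, ``t_end`` and ``type``
    attributes and be time-ordered.
    """
    good = [
        p for p in peaks
        if p.is_good
        and not any(ev.t_start <= p.t_peak <= ev.t_end for ev in interrupting_events)
    ]
    if len(good) < config.min_peaks:
        return []
    times = np.asarray(times, dtype=float)
    speed = np.asarray(speed, dtype=float)

    chains: list[tuple[list[SpeedPeak], str]] = []
    chain = [good[0]]
    for prev, nxt in zip(good[:-1], good[1:]):
        cause = None
        if nxt.t_peak - prev.t_peak > config.max_gap:
            cause = "gap"
        else:
            cause = _interrupting_between(prev.t_peak, nxt.t_peak, interrupting_events)
        if cause is None:
            chain.append(nxt)
        else:
            chains.append((chain, cause))
            chain = [nxt]
    chains.append((chain, "track_end"))

    runs: list[RunRecord] = []
    for members, cause in chains:
        if len(members) < config.min_peaks:
            continue
        t0 = members[0].left_bound
        t1 = members[-1].right_bound
        # a flanking minimum may fall inside an adjacent interrupting
        # event; pull the boundary back so the event stays outside the run
        for ev in interrupting_events:
            if ev.t_end <= members[0].t_peak:
                t0 = max(t0, ev.t_end)
            if ev.t_start >= members[-1].t_peak:
                t1 = min(t1, ev.t_start)
        seg = (times >= t0) & (times <= t1)
        f_hat, reliable = stride_frequency(times[seg], speed[seg], config)
        runs.append(
            RunRecord(
                larva_id=larva_id,
                t_start=float(t0),
                t_end=float(t1),
                n_strides=len(members),
                mean_max_stride_speed=float(np.mean([p.amplitude for p in members])),
                stride_frequency=f_hat,
                terminated_by=cause,
                frequency_reliable=reliable,
            )
        )
    return runs
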