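"""Hysteresis (Schmitt-trigger) event detection for rolls, head casts and hunches.

A behavioral action appears as a significant peak (or well) in one posture
variable: rolls are peaks in crabspeed, head casts are peaks/wells in the
head angle, hunches are wells in the midline length.  Detection uses an
extended Schmitt trigger with four thresholds per action:

* ``upper`` -- an event opens when the absolute signal rises to this level;
* ``lower`` -- an event closes when the absolute signal falls below it
  (hysteresis: ``upper >= lower`` suppresses chatter around one level);
* ``width`` -- a single event shorter than this is discarded;
* ``gap`` -- two or more same-polarity events closer than this merge into
  one, kept if the merged span reaches ``width``.

Event boundaries sit on samples: an event starts at the first sample at or
above ``upper`` and ends at the last sample still at or above ``lower``
(no sub-sample interpolation; at the nominal 15 fps this is the native
resolution of the data).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SchmittThresholds",
    "EventRecord",
    "EventSignal",
    "ThresholdTuningResult",
    "schmitt_detect",
    "detect_rolls",
    "detect_casts",
    "detect_hunches",
    "event_frequency",
    "detection_rates",
    "tune_thresholds",
    "DEFAULT_ROLL_THRESHOLDS",
    "DEFAULT_CAST_THRESHOLDS",
    "DEFAULT_HUNCH_THRESHOLDS",
]


@dataclass(frozen=True)
class SchmittThresholds:
    """Four-threshold configuration of the extended Schmitt trigger.

    Parameters
    ----------
    upper, lower:
        Amplitude thresholds in the units of the monitored signal
        (mm/s for crabspeed, degrees for head angle, mm for midline
        deviation).  ``upper >= lower > 0``.
    width:
        Minimum event duration in seconds.
    gap:
        Maximum separation in seconds below which adjacent same-polarity
        events merge.
    """

    upper: float
    lower: float
    width: float
    gap: float

    def __post_init__(self) -> None:
        if not (self.upper >= self.lower > 0):
            raise ValueError(
                f"require upper >= lower > 0, got upper={self.upper}, lower={self.lower}"
            )
        if self.width <= 0 or self.gap <= 0:
            raise ValueError("width and gap thresholds must be positive")


#: Published default thresholds per action (signal units, s).
DEFAULT_ROLL_THRESHOLDS = SchmittThresholds(upper=2.8, lower=1.8, width=0.12, gap=1.0)
DEFAULT_CAST_THRESHOLDS = SchmittThresholds(upper=27.0, lower=20.0, width=0.15, gap=0.67)
DEFAULT_HUNCH_THRESHOLDS = SchmittThresholds(upper=0.19, lower=0.09, width=0.2, gap=0.3)


@dataclass
class EventRecord:
    """One detected (or ground-truth) action."""

    larva_id: str
    type: str  # roll | cast_left | cast_right | hunch | run (truth only)
    t_start: float
    t_end: float
    duration: float
    amplitude: float
    polarity: str = "peak"  # peak | well
    truncated: bool = False  # closed by the end of the track, not the signal

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end must not precede t_start")

    def contains(self, other: "EventRecord") -> bool:
        """True if ``other`` lies fully inside this event's interval."""
        return self.t_start <= other.t_start and other.t_end <= self.t_end


@dataclass
class EventSignal:
    """Signal that equals the event amplitude inside events and 0 outside."""

    times: np.ndarray
    values: np.ndarray


def _raw_events(y: np.ndarray, upper: float, lower: float) -> tuple[list[tuple[int, int]], bool]:
    """Index pairs [start, end] of supra-threshold excursions of ``y``.

    Opens at the first sample with ``y >= upper``; closes at the last sample
    with ``y >= lower`` before ``y`` drops below ``lower``.  Returns the raw
    event list and whether the final event was still open at the array end.
    """
    events: list[tuple[int, int]] = []
    open_at: int | None = None
    for i, v in enumerate(y):
        if open_at is None:
            if v >= upper:
                open_at = i
        elif v < lower:
            events.append((open_at, i - 1))
            open_at = None
    truncated = open_at is not None
    if truncated:
        events.append((open_at, len(y) - 1))
    return events, truncated


def _merge_and_filter(
    raw: list[tuple[int, int]],
    times: np.ndarray,
    thr: SchmittThresholds,
) -> list[tuple[int, int]]:
    """Apply the gap-merging and width rules to raw index intervals.

    The gap rule chains left-to-right transitively: a sequence of raw events
    each closer than ``gap`` to its neighbour collapses into one candidate
    spanning from the first start to the last end.  A candidate survives if
    its span is at least ``width``.
    """
    merged: list[tuple[int, int]] = []
    i = 0
    while i < len(raw):
        s, e = raw[i]
        j = i + 1
        while j < len(raw) and times[raw[j][0]] - times[e] < thr.gap:
            e = raw[j][1]
            j += 1
        if times[e] - times[s] >= thr.width:
            merged.append((s, e))
        i = j
    return merged


def schmitt_detect(
    times: np.ndarray,
    values: np.ndarray,
    thr: SchmittThresholds,
    polarity: str = "peaks",
    larva_id: str = "",
    event_type: str = "event",
    well_type: str | None = None,
) -> tuple[list[EventRecord], EventSignal]:
    """Detect events in a non-oscillating signal with the extended trigger.

    Parameters
    ----------
    times, values:
        Time-ordered signal; NaNs are treated as 0 (outside any event).
    polarity:
        ``"peaks"`` detects positive excursions, ``"wells"`` negative ones,
        ``"both"`` detects both and labels each record's ``polarity``.
    event_type, well_type:
        Type label given to peak events and (for ``polarity="both"``) to
        well events; ``well_type`` defaults to ``event_type``.

    Returns
    -------
    (events, event_signal):
        Events sorted by start time, and the event signal (amplitude inside
        events, 0 outside).
    """
    times = np.asarray(times, dtype=float)
    vals = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    if times.shape != vals.shape:
        raise ValueError("times and values must have matching shapes")
    if polarity not in ("peaks", "wells", "both"):
        raise ValueError(f"unknown polarity {polarity!r}")

    signs: list[tuple[int, str, str]] = []
    if polarity in ("peaks", "both"):
        signs.append((1, "peak", event_type))
    if polarity in ("wells", "both"):
        signs.append((-1, "well", well_type or event_type))

    events: list[EventRecord] = []
    signal = np.zeros_like(vals)
    for sign, pol, etype in signs:
        raw, open_at_end = _raw_events(sign * vals, thr.upper, thr.lower)
        kept = _merge_and_filter(raw, times, thr)
        last_raw_end = raw[-1][1] if raw else -1
        for s, e in kept:
            amp = float(np.max(np.abs(vals[s : e + 1])))
            events.append(
                EventRecord(
                    larva_id=larva_id,
                    type=etype,
                    t_start=float(times[s]),
                    t_end=float(times[e]),
                    duration=float(times[e] - times[s]),
                    amplitude=amp,
                    polarity=pol,
                    truncated=open_at_end and e == last_raw_end,
                )
            )
            signal[s : e + 1] = amp
    events.sort(key=lambda ev: (ev.t_start, ev.polarity))
    return events, EventSignal(times=times, values=signal)


def detect_rolls(
    posture,
    thr: SchmittThresholds = DEFAULT_ROLL_THRESHOLDS,
) -> list[EventRecord]:
    """Detect rolls as significant peaks in the crabspeed series."""
    crab = np.asarray(posture.crabspeed, dtype=float)
    if not np.isfinite(crab).any():
        logger.warning("larva %s: crabspeed entirely missing, no rolls", posture.larva_id)
        return []
    events, _ = schmitt_detect(
        posture.times, crab, thr, polarity="peaks",
        larva_id=posture.larva_id, event_type="roll",
    )
    return events


def _discard_inside_rolls(
    candidates: list[EventRecord], rolls: Sequence[EventRecord]
) -> list[EventRecord]:
    # Rolls corrupt the posture geometry; cast/hunch candidates fully inside
    # a roll interval are vetting artifacts, not actions.
    kept = []
    for ev in candidates:
        if any(r.larva_id == ev.larva_id and r.contains(ev) for r in rolls):
            continue
        kept.append(ev)
    return kept


def detect_casts(
    posture,
    thr: SchmittThresholds = DEFAULT_CAST_THRESHOLDS,
    concurrent_rolls: Sequence[EventRecord] = (),
) -> list[EventRecord]:
    """Detect head casts in the signed head-angle series.

    Peaks (positive excursions) are left casts, wells right casts, following
    the positive-equals-left sign convention of the posture metrics.
    Candidates fully inside a roll interval are discarded.
    """
    angle = np.asarray(posture.head_angle, dtype=float)
    if not np.isfinite(angle).any():
        logger.warning("larva %s: head angle entirely missing, no casts", posture.larva_id)
        return []
    events, _ = schmitt_detect(
        posture.times, angle, thr, polarity="both",
        larva_id=posture.larva_id, event_type="cast_left", well_type="cast_right",
    )
    return _discard_inside_rolls(events, concurrent_rolls)


def running_median_baseline(
    times: np.ndarray, values: np.ndarray, window: float = 5.0
) -> np.ndarray:
    """Running median of ``values`` over a ``window``-second span.

    The window is converted to an odd sample count via the median sampling
    interval.  Tracks shorter than the window fall back to the per-track
    median (with a warning), which still removes the constant offset.
    """
    times = np.asarray(times, dtype=float)
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        return np.full_like(vals, np.nan)
    filled = np.where(finite, vals, np.median(vals[finite]))
    if len(times) < 2:
        return filled
    dt = float(np.median(np.diff(times)))
    k = max(1, int(round(window / dt)))
    if k % 2 == 0:
        k += 1
    if k >= len(vals):
        logger.warning(
            "track shorter than %.1f s baseline window; using per-track median", window
        )
        return np.full_like(vals, float(np.median(filled)))
    return ndimage.median_filter(filled, size=k, mode="nearest")


def detect_hunches(
    posture,
    thr: SchmittThresholds = DEFAULT_HUNCH_THRESHOLDS,
    concurrent_rolls: Sequence[EventRecord] = (),
    baseline_window: float = 5.0,
) -> list[EventRecord]:
    """Detect hunches as wells in the baseline-referenced midline length.

    The baseline is a per-animal running median over ``baseline_window``
    seconds; deviations (midline minus baseline) isolate brief retractions
    from slow length drift.  Candidates inside rolls are discarded.
    """
    midline = np.asarray(posture.midline, dtype=float)
    if not np.isfinite(midline).any():
        logger.warning("larva %s: midline entirely missing, no hunches", posture.larva_id)
        return []
    baseline = running_median_baseline(posture.times, midline, window=baseline_window)
    deviation = midline - baseline
    events, _ = schmitt_detect(
        posture.times, deviation, thr, polarity="wells",
        larva_id=posture.larva_id, event_type="hunch",
    )
    return _discard_inside_rolls(events, concurrent_rolls)


def event_frequency(events: Iterable[EventRecord], t0: float, t1: float) -> int:
    """Count events whose start falls in the half-open interval [t0, t1)."""
    if t1 < t0:
        raise ValueError("interval end precedes start")
    return sum(1 for ev in events if t0 <= ev.t_start < t1)


# ---------------------------------------------------------------------------
# detection-vs-truth scoring and threshold tuning
# ---------------------------------------------------------------------------


def _overlap(a: EventRecord, b: EventRecord) -> float:
    return max(0.0, min(a.t_end, b.t_end) - max(a.t_start, b.t_start))


def detection_rates(
    detected: Sequence[EventRecord],
    truth: Sequence[EventRecord],
    match_overlap: float = 0.5,
) -> dict:
    """Score detections against ground truth by greedy interval matching.

    A detection matches an unmatched truth event of the same larva and type
    when their temporal overlap is at least ``match_overlap`` of the shorter
    interval.  Detections are processed in start-time order, each taking the
    best-overlapping eligible truth event.

    Returns a dict with ``tp``, ``fp``, ``fn``, ``fdr``, ``fnr`` and the
    matched ``pairs``.  Rates are fractions (0..1); NaN when undefined.
    """
    truth = sorted(truth, key=lambda ev: ev.t_start)
    matched_truth = [False] * len(truth)
    pairs: list[tuple[EventRecord, EventRecord]] = []
    fp = 0
    for det in sorted(detected, key=lambda ev: ev.t_start):
        best_j, best_ov = -1, 0.0
        for j, tru in enumerate(truth):
            if matched_truth[j] or tru.larva_id != det.larva_id or tru.type != det.type:
                continue
            shorter = max(min(det.duration, tru.duration), 1e-12)
            ov = _overlap(det, tru)
            if ov >= match_overlap * shorter and ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0:
            matched_truth[best_j] = True
            pairs.append((det, truth[best_j]))
        else:
            fp += 1
    tp = len(pairs)
    fn = matched_truth.count(False)
    fdr = fp / (tp + fp) if tp + fp else float("nan")
    fnr = fn / (tp + fn) if tp + fn else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "fdr": fdr, "fnr": fnr, "pairs": pairs}


@dataclass
class ThresholdTuningResult:
    thresholds: SchmittThresholds
    fdr: float
    fnr: float
    compliant: bool


def tune_thresholds(
    signals: Mapping[str, tuple[np.ndarray, np.ndarray]],
    truth: Sequence[EventRecord],
    polarity: str,
    grid: Mapping[str, Sequence[float]],
    event_type: str = "event",
    well_type: str | None = None,
    max_fdr: float = 0.05,
    max_fnr: float = 0.15,
    min_examples: int = 30,
    match_overlap: float = 0.5,
) -> ThresholdTuningResult:
    """Grid-search Schmitt thresholds against expert-labeled ground truth.

    Mirrors the iterative manual tuning procedure: candidate threshold sets
    are tried in the given grid order (lexicographic over
    ``upper x lower x width x gap``) and the first set with false detection
    rate below ``max_fdr`` AND false negative rate below ``max_fnr`` is
    returned.  If no set qualifies, the set minimizing ``fdr + fnr`` is
    returned flagged non-compliant.

    ``signals`` maps larva_id to ``(times, values)`` of the monitored
    variable.  Positive instances are the labeled events; negative instances
    are counted as label-free gaps at least as long as the median labeled
    duration.  Fewer than ``min_examples`` of either only triggers a
    warning for negatives but is an error for positives.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty label set")
    if len(truth) < min_examples:
        raise ValueError(
            f"need at least {min_examples} positive labeled instances, got {len(truth)}"
        )
    med_dur = float(np.median([ev.duration for ev in truth]))
    n_neg = 0
    for lid, (times, _vals) in signals.items():
        bounds = [times[0]] + sorted(
            itertools.chain.from_iterable(
                (ev.t_start, ev.t_end) for ev in truth if ev.larva_id == lid
            )
        ) + [times[-1]]
        starts, ends = bounds[0::2], bounds[1::2]
        n_neg += sum(1 for s, e in zip(starts, ends) if e - s >= med_dur)
    if n_neg < min_examples:
        logger.warning(
            "only %d negative (label-free) instances, fewer than %d", n_neg, min_examples
        )

    best: ThresholdTuningResult | None = None
    for upper, lower, width, gap in itertools.product(
        grid["upper"], grid["lower"], grid["width"], grid["gap"]
    ):
        if not (upper >= lower > 0):
            continue
        thr = SchmittThresholds(upper, lower, width, gap)
        detected: list[EventRecord] = []
        for lid, (times, vals) in signals.items():
            evs, _ = schmitt_detect(
                times, vals, thr, polarity=polarity,
                larva_id=lid, event_type=event_type, well_type=well_type,
            )
            detected.extend(evs)
        rates = detection_rates(detected, truth, match_overlap=match_overlap)
        fdr = 0.0 if np.isnan(rates["fdr"]) else rates["fdr"]
        fnr = 1.0 if np.isnan(rates["fnr"]) else rates["fnr"]
        result = ThresholdTuningResult(thr, fdr, fnr, fdr < max_fdr and fnr < max_fnr)
        if result.compliant:
            logger.info(
                "tuning: compliant thresholds %s (FDR %.1f%%, FNR %.1f%%)",
                thr, 100 * fdr, 100 * fnr,
            )
            return result
        if best is None or fdr + fnr < best.fdr + best.fnr:
            best = result
    assert best is not None
    logger.warning(
        "tuning: no grid point met FDR<%.0f%% and FNR<%.0f%%; best %s "
        "(FDR %.1f%%, FNR %.1f%%) returned non-compliant",
        100 * max_fdr, 100 * max_fnr, best.thresholds, 100 * best.fdr, 100 * best.fnr,
    )
    return best
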