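"""Reading/writing tracking data, event tables, posture tables and config.

Track dialect
-------------
A long-format TSV/CSV table, one row per (larva, frame), readable in any
table tool:

``larva_id, t, x, y [, spine_x0, spine_y0, .., spine_x10, spine_y10]
[, outline_left, outline_right]``

Units are millimetres and seconds.  Spine index 0 is the tail, index 10
the head.  Outline cells hold semicolon-joined ``x,y`` pairs ordered tail
to head along each body side.  Raw video is never part of the format; the
pipeline starts from tracked geometry.

Track-inclusion filters
-----------------------
Objects tracked for less than 5 s, or that moved less than one body length
(maximum centroid excursion from the starting point, in units of the
animal's median midline length), are rejected as debris or lost tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .event_detection import (
    DEFAULT_CAST_THRESHOLDS,
    DEFAULT_HUNCH_THRESHOLDS,
    DEFAULT_ROLL_THRESHOLDS,
    EventRecord,
    SchmittThresholds,
)
from .stride_runs import RunConfig, RunRecord

logger = logging.getLogger(__name__)

N_SPINE = 11

__all__ = [
    "TrackRecord",
    "Experiment",
    "ThresholdConfig",
    "ParseError",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
    "read_events",
    "write_events",
    "read_posture",
    "write_posture",
]


class ParseError(ValueError):
    """A track file violates the dialect or a track invariant."""


@dataclass(eq=False)
class TrackRecord:
    """One larva's tracked geometry over time.

    ``times`` are strictly increasing seconds (uneven sampling allowed,
    nominally 1/15 s).  ``centroid`` is (n, 2) in mm.  ``spine`` is
    (n, 11, 2) tail-to-head, optional.  ``outline_left``/``outline_right``
    are per-frame (k, 2) arrays, optional, each side with >= 11 points.
    """

    larva_id: str
    times: np.ndarray
    centroid: np.ndarray
    spine: np.ndarray | None = None
    outline_left: list[np.ndarray] | None = None
    outline_right: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.times.ndim != 1 or self.centroid.shape != (len(self.times), 2):
            raise ValueError(f"larva {self.larva_id}: malformed times/centroid")
        bad = np.flatnonzero(np.diff(self.times) <= 0)
        if bad.size:
            raise ParseError(
                f"larva {self.larva_id}: non-monotone times at row {int(bad[0]) + 1}"
            )
        if self.spine is not None:
            self.spine = np.asarray(self.spine, dtype=float)
            if self.spine.shape != (len(self.times), N_SPINE, 2):
                raise ParseError(
                    f"larva {self.larva_id}: spine must have {N_SPINE} points per frame"
                )
        for side, name in ((self.outline_left, "left"), (self.outline_right, "right")):
            if side is not None and any(len(p) < N_SPINE for p in side):
                raise ParseError(
                    f"larva {self.larva_id}: {name} outline has fewer than "
                    f"{N_SPINE} points in some frame"
                )

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def body_length(self, fallback: float = 4.0) -> float:
        """Median midline length over the track; ``fallback`` mm if no spine."""
        if self.spine is None:
            return fallback
        seg = np.linalg.norm(np.diff(self.spine, axis=1), axis=2).sum(axis=1)
        return float(np.median(seg))


@dataclass
class Experiment:
    """A cohort of tracks sharing one time origin and stimulus schedule."""

    tracks: dict[str, TrackRecord]
    stimulus_onset: float = 0.0
    stimulus_duration: float = 0.0
    frame_rate_nominal: float = 15.0

    def __post_init__(self) -> None:
        if self.tracks:
            t0 = min(tr.times[0] for tr in self.tracks.values())
            t1 = max(tr.times[-1] for tr in self.tracks.values())
            if not (t0 <= self.stimulus_onset <= t1):
                logger.warning(
                    "stimulus onset %.2f s outside recorded span [%.2f, %.2f] s",
                    self.stimulus_onset, t0, t1,
                )


@dataclass
class ThresholdConfig:
    """Per-action Schmitt thresholds plus run-detection parameters."""

    roll: SchmittThresholds = field(default_factory=lambda: DEFAULT_ROLL_THRESHOLDS)
    cast: SchmittThresholds = field(default_factory=lambda: DEFAULT_CAST_THRESHOLDS)
    hunch: SchmittThresholds = field(default_factory=lambda: DEFAULT_HUNCH_THRESHOLDS)
    run: RunConfig = field(default_factory=RunConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for action in ("roll", "cast", "hunch"):
            if action in raw:
                kwargs[action] = SchmittThresholds(**raw[action])
        if "run" in raw:
            kwargs["run"] = RunConfig(**raw["run"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        out = {
            action: {
                "upper": float(thr.upper), "lower": float(thr.lower),
                "width": float(thr.width), "gap": float(thr.gap),
            }
            for action, thr in (("roll", self.roll), ("cast", self.cast), ("hunch", self.hunch))
        }
        out["run"] = {
            "abs_floor": float(self.run.abs_floor),
            "rel_fraction": float(self.run.rel_fraction),
            "min_peaks": int(self.run.min_peaks),
            "max_gap": float(self.run.max_gap),
            "f_min": float(self.run.f_min),
            "f_max": float(self.run.f_max),
            "oversampling": int(self.run.oversampling),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------

_SPINE_COLS = [f"spine_{ax}{k}" for k in range(N_SPINE) for ax in ("x", "y")]


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_outline(cell: str) -> np.ndarray:
    pts = [pair.split(",") for pair in cell.split(";") if pair]
    return np.array([[float(x), float(y)] for x, y in pts])


def _format_outline(points: np.ndarray) -> str:
    return ";".join(f"{float(x)!r},{float(y)!r}" for x, y in points)


def read_tracks(
    path: str | Path,
    dialect: str = "tsv",
    stimulus_onset: float = 0.0,
    stimulus_duration: float = 0.0,
    frame_rate_nominal: float = 15.0,
) -> Experiment:
    """Read a track table into an :class:`Experiment`.

    Rows with missing mandatory fields (``t``, ``x``, ``y``) are rejected
    and counted; nothing is dropped silently.  Missing spine/outline
    columns yield records with those fields absent (warning logged).
    Non-monotone times or a wrong spine point count raise
    :class:`ParseError` naming the larva.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"larva_id": str},
                     float_precision="round_trip")
    required = {"larva_id", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ParseError(f"track file lacks required columns {sorted(required - set(df.columns))}")
    n_in = len(df)
    ok = df[["t", "x", "y"]].notna().all(axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d rows with missing t/x/y", n_rejected)
    df = df[ok]
    logger.info("track rows: %d read = %d parsed + %d rejected", n_in, len(df), n_rejected)

    has_spine = all(c in df.columns for c in _SPINE_COLS)
    has_outline = {"outline_left", "outline_right"}.issubset(df.columns)
    if not has_spine:
        logger.warning("no spine columns: spine-based metrics will be unavailable")
    if not has_outline:
        logger.warning("no outline columns: width will be unavailable")

    tracks: dict[str, TrackRecord] = {}
    for larva_id, grp in df.groupby("larva_id", sort=True):
        times = grp["t"].to_numpy(dtype=float)
        centroid = grp[["x", "y"]].to_numpy(dtype=float)
        spine = None
        if has_spine and grp[_SPINE_COLS].notna().all(axis=None):
            spine = grp[_SPINE_COLS].to_numpy(dtype=float).reshape(len(grp), N_SPINE, 2)
        ol = orr = None
        if has_outline and grp["outline_left"].notna().all():
            ol = [_parse_outline(c) for c in grp["outline_left"]]
            orr = [_parse_outline(c) for c in grp["outline_right"]]
        tracks[str(larva_id)] = TrackRecord(
            larva_id=str(larva_id), times=times, centroid=centroid,
            spine=spine, outline_left=ol, outline_right=orr,
        )
    return Experiment(
        tracks=tracks,
        stimulus_onset=stimulus_onset,
        stimulus_duration=stimulus_duration,
        frame_rate_nominal=frame_rate_nominal,
    )


def write_tracks(exp: Experiment, path: str | Path, dialect: str = "tsv") -> None:
    """Write an :class:`Experiment` in the track dialect (round-trip safe)."""
    frames = []
    for larva_id in sorted(exp.tracks):
        tr = exp.tracks[larva_id]
        data = {"larva_id": tr.larva_id, "t": tr.times, "x": tr.centroid[:, 0], "y": tr.centroid[:, 1]}
        if tr.spine is not None:
            flat = tr.spine.reshape(len(tr.times), -1)
            for j, col in enumerate(_SPINE_COLS):
                data[col] = flat[:, j]
        if tr.outline_left is not None and tr.outline_right is not None:
            data["outline_left"] = [_format_outline(p) for p in tr.outline_left]
            data["outline_right"] = [_format_outline(p) for p in tr.outline_right]
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["larva_id", "t", "x", "y"]
    )
    out.to_csv(path, sep=_sep(dialect), index=False)


def filter_tracks(
    exp: Experiment,
    min_duration: float = 5.0,
    min_displacement: float = 1.0,
    body_length_fallback: float = 4.0,
) -> Experiment:
    """Apply the track-inclusion filters.

    Keeps tracks spanning at least ``min_duration`` seconds whose maximum
    centroid excursion from the starting point reaches at least
    ``min_displacement`` body lengths (median midline length, or
    ``body_length_fallback`` mm for centroid-only tracks).  Idempotent;
    an empty result is returned as an empty experiment, not an error.
    """
    kept: dict[str, TrackRecord] = {}
    n_short = n_still = 0
    for larva_id, tr in exp.tracks.items():
        if tr.span < min_duration:
            n_short += 1
            continue
        excursion = float(np.max(np.linalg.norm(tr.centroid - tr.centroid[0], axis=1)))
        if excursion < min_displacement * tr.body_length(fallback=body_length_fallback):
            n_still += 1
            continue
        kept[larva_id] = tr
    logger.info(
        "track filter: %d kept, %d rejected (<%.0f s), %d rejected (<%.1f body length)",
        len(kept), n_short, min_duration, n_still,
    )
    return replace(exp, tracks=kept)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

_EVENT_COLS = [
    "larva_id", "type", "t_start", "t_end", "duration", "amplitude",
    "polarity", "truncated", "n_strides", "mean_max_stride_speed",
    "stride_frequency", "terminated_by",
]


def write_events(records: Sequence[EventRecord | RunRecord], path: str | Path) -> None:
    """Write events and runs to one CSV table with a fixed column order.

    Run rows carry the run-only columns (``n_strides``,
    ``mean_max_stride_speed``, ``stride_frequency``, ``terminated_by``);
    event rows carry amplitude/polarity/truncated.  Overlapping same-type
    events of one larva trigger a warning (possible detector misuse).
    """
    rows = []
    for rec in records:
        if isinstance(rec, RunRecord):
            rows.append({
                "larva_id": rec.larva_id, "type": "run",
                "t_start": rec.t_start, "t_end": rec.t_end,
                "duration": rec.t_end - rec.t_start,
                "n_strides": rec.n_strides,
                "mean_max_stride_speed": rec.mean_max_stride_speed,
                "stride_frequency": rec.stride_frequency,
                "terminated_by": rec.terminated_by,
            })
        else:
            rows.append({
                "larva_id": rec.larva_id, "type": rec.type,
                "t_start": rec.t_start, "t_end": rec.t_end,
                "duration": rec.duration, "amplitude": rec.amplitude,
                "polarity": rec.polarity, "truncated": int(rec.truncated),
            })
    df = pd.DataFrame(rows, columns=_EVENT_COLS)
    _warn_overlaps(records)
    df.to_csv(path, index=False)


def _warn_overlaps(records: Sequence) -> None:
    evs = [r for r in records if not isinstance(r, RunRecord)]
    by_key: dict[tuple[str, str], list] = {}
    for ev in evs:
        by_key.setdefault((ev.larva_id, ev.type), []).append(ev)
    for (larva_id, etype), group in by_key.items():
        group = sorted(group, key=lambda e: e.t_start)
        for a, b in zip(group[:-1], group[1:]):
            if b.t_start < a.t_end:
                logger.warning(
                    "overlapping %s events for larva %s at %.2f s", etype, larva_id, b.t_start
                )
                break


def read_events(path: str | Path) -> list[EventRecord | RunRecord]:
    """Read an event table written by :func:`write_events` (round-trip safe)."""
    df = pd.read_csv(path, dtype={"larva_id": str}, float_precision="round_trip")
    records: list[EventRecord | RunRecord] = []
    for _, row in df.iterrows():
        if row["type"] == "run":
            records.append(RunRecord(
                larva_id=row["larva_id"],
                t_start=float(row["t_start"]), t_end=float(row["t_end"]),
                n_strides=int(row["n_strides"]),
                mean_max_stride_speed=float(row["mean_max_stride_speed"]),
                stride_frequency=float(row["stride_frequency"]),
                terminated_by=str(row["terminated_by"]),
            ))
        else:
            records.append(EventRecord(
                larva_id=row["larva_id"], type=row["type"],
                t_start=float(row["t_start"]), t_end=float(row["t_end"]),
                duration=float(row["duration"]), amplitude=float(row["amplitude"]),
                polarity=str(row["polarity"]), truncated=bool(int(row["truncated"])),
            ))
    return records


# ---------------------------------------------------------------------------
# posture tables
# ---------------------------------------------------------------------------

_POSTURE_COLS = ["larva_id", "t", "speed", "crabspeed", "midline", "width", "head_angle"]


def write_posture(series: Iterable, path: str | Path, dialect: str = "tsv") -> None:
    """Write posture series (one row per larva and time, NA for missing)."""
    frames = [s.to_frame() for s in series]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_POSTURE_COLS)
    out.to_csv(path, sep=_sep(dialect), index=False, na_rep="NA")


def read_posture(path: str | Path, dialect: str = "tsv") -> list:
    """Read a posture table back into :class:`PostureSeries` objects."""
    from .posture_metrics import PostureSeries

    df = pd.read_csv(path, sep=_sep(dialect), dtype={"larva_id": str},
                     na_values=["NA"], float_precision="round_trip")
    out = []
    for larva_id, grp in df.groupby("larva_id", sort=True):
        out.append(PostureSeries(
            larva_id=str(larva_id),
            times=grp["t"].to_numpy(dtype=float),
            speed=grp["speed"].to_numpy(dtype=float),
            crabspeed=grp["crabspeed"].to_numpy(dtype=float),
            midline=grp["midline"].to_numpy(dtype=float),
            width=grp["width"].to_numpy(dtype=float),
            head_angle=grp["head_angle"].to_numpy(dtype=float),
        ))
    return out
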