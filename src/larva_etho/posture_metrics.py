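"""Per-time posture variables from tracked larval geometry.

Five variables drive all downstream action detection:

* **speed** (mm/s) -- centroid displacement over a short bracket around
  each time point, divided by the bracket span;
* **crabspeed** (mm/s) -- the magnitude of the same displacement's
  component perpendicular to the body axis (sideways speed; large during
  rolls);
* **midline** (mm) -- total Euclidean length along the 11-point spine;
* **width** (mm) -- mean of the local outline-to-outline widths at the
  central 60% of the spine points;
* **head angle** (degrees, signed) -- deflection of the head tip from the
  least-squares line through the posterior spine, positive for a LEFT
  cast (so peaks in the series are left casts, wells right casts).

The displacement bracket starts at ``t +- T/2`` (``T`` = 0.1 s) and is
shrunk inward one sample per step while the chord keeps growing -- a fast
heuristic for the maximal chord, robust to the direction reversals that
rolls and casts put inside the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PostureSeries",
    "DisplacementBracket",
    "total_least_squares_line",
    "displacement_bracket",
    "compute_speed",
    "compute_crabspeed",
    "compute_midline",
    "compute_width",
    "compute_head_angle",
    "compute_posture",
]


@dataclass
class PostureSeries:
    """The five posture variables of one larva, aligned to ``times``.

    Missing values (e.g. speed within T/2 of the track ends) are NaN.
    """

    larva_id: str
    times: np.ndarray
    speed: np.ndarray
    crabspeed: np.ndarray
    midline: np.ndarray
    width: np.ndarray
    head_angle: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "larva_id": self.larva_id,
                "t": self.times,
                "speed": self.speed,
                "crabspeed": self.crabspeed,
                "midline": self.midline,
                "width": self.width,
                "head_angle": self.head_angle,
            }
        )


@dataclass
class DisplacementBracket:
    """Final displacement bracket around one time point."""

    t_a: float
    t_b: float
    i_a: int
    i_b: int
    chord: np.ndarray  # displacement vector p(t_b) - p(t_a), mm

    @property
    def chord_length(self) -> float:
        return float(np.hypot(*self.chord))

    @property
    def span(self) -> float:
        return self.t_b - self.t_a


def total_least_squares_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Total-least-squares line fit: returns ``(centroid, unit_direction)``.

    None for degenerate input (fewer than 2 points or zero spatial extent).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return None
    c = pts.mean(axis=0)
    centered = pts - c
    if not np.any(np.abs(centered) > 1e-12):
        return None
    # direction = leading right singular vector of the centered coordinates
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return c, vt[0]


def _nearest_index(times: np.ndarray, t: float) -> int:
    i = int(np.searchsorted(times, t))
    if i <= 0:
        return 0
    if i >= len(times):
        return len(times) - 1
    return i if times[i] - t < t - times[i - 1] else i - 1


def displacement_bracket(track, t: float, T: float = 0.1) -> DisplacementBracket | None:
    """Shrinking displacement bracket around time ``t``.

    Starts from the samples nearest ``t - T/2`` and ``t + T/2`` (forced to
    strictly bracket the sample nearest ``t``), then moves both ends inward
    one sample at a time while they still bracket ``t`` and the chord
    length strictly increases.  Returns None (missing value) when ``t`` is
    within ``T/2`` of either track end or fewer than 3 samples fall in the
    initial window.
    """
    times = np.asarray(track.times, dtype=float)
    pos = np.asarray(track.centroid, dtype=float)
    n = len(times)
    if n < 3 or t - T / 2 < times[0] or t + T / 2 > times[-1]:
        return None
    i = _nearest_index(times, t)
    ia = min(_nearest_index(times, t - T / 2), i - 1)
    ib = max(_nearest_index(times, t + T / 2), i + 1)
    if ia < 0 or ib > n - 1:
        return None
    chord = float(np.linalg.norm(pos[ib] - pos[ia]))
    while ia + 1 < i and ib - 1 > i:
        c2 = float(np.linalg.norm(pos[ib - 1] - pos[ia + 1]))
        if c2 > chord:
            ia, ib, chord = ia + 1, ib - 1, c2
        else:
            break
    return DisplacementBracket(
        t_a=float(times[ia]), t_b=float(times[ib]), i_a=ia, i_b=ib,
        chord=pos[ib] - pos[ia],
    )


def compute_speed(track, t: float, T: float = 0.1, span: str = "final") -> float:
    """Centroid speed at ``t``: bracket chord length over the bracket span.

    ``span="final"`` divides by the span of the final (possibly shrunk)
    bracket for dimensional consistency; ``span="fixed"`` divides by the
    nominal integration time ``T`` instead.
    """
    br = displacement_bracket(track, t, T)
    if br is None:
        return float("nan")
    denom = br.span if span == "final" else T
    return br.chord_length / denom


def _body_axis(track, i: int) -> np.ndarray | None:
    """Unit body-axis vector at frame ``i`` from a TLS line through the
    outline points when present, else through the spine points."""
    if track.outline_left is not None and track.outline_right is not None:
        pts = np.vstack([track.outline_left[i], track.outline_right[i]])
    elif track.spine is not None:
        pts = track.spine[i]
    else:
        return None
    fit = total_least_squares_line(pts)
    return None if fit is None else fit[1]


def compute_crabspeed(track, t: float, T: float = 0.1, span: str = "final") -> float:
    """Sideways (perpendicular-to-body-axis) speed at ``t``."""
    br = displacement_bracket(track, t, T)
    if br is None:
        return float("nan")
    b = _body_axis(track, _nearest_index(np.asarray(track.times), t))
    if b is None:
        return float("nan")
    perp = br.chord - np.dot(br.chord, b) * b
    denom = br.span if span == "final" else T
    return float(np.linalg.norm(perp)) / denom


def compute_midline(spine: np.ndarray) -> float:
    """Total Euclidean distance along the spine points (mm)."""
    pts = np.asarray(spine, dtype=float)
    if len(pts) < 2:
        raise ValueError("midline needs at least 2 spine points")
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if length == 0.0:
        logger.warning("degenerate spine: all points identical, midline 0")
    return length


def _boxcar5(points: np.ndarray) -> np.ndarray:
    """5-point boxcar average along the point sequence (edges shortened)."""
    pts = np.asarray(points, dtype=float)
    out = np.empty_like(pts)
    n = len(pts)
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def _width_window(n_side: int, k: int, m: int) -> np.ndarray:
    """Outline indices i with n_side*(k-1)/m < i < n_side*(k+1)/m, clamped
    to at least one index (the proportional position) when empty."""
    lo = n_side * (k - 1) / m
    hi = n_side * (k + 1) / m
    idx = np.arange(max(0, int(np.floor(lo)) ), min(n_side, int(np.ceil(hi))))
    idx = idx[(idx > lo) & (idx < hi)]
    if idx.size == 0:
        idx = np.array([min(n_side - 1, max(0, round(n_side * k / m)))])
    return idx


def compute_width(
    outline_left: np.ndarray, outline_right: np.ndarray, spine: np.ndarray
) -> float:
    """Morphological width (mm) from smoothed left/right outline points.

    Each side is 5-point boxcar smoothed.  The local width at spine point
    ``k`` is the minimum distance between smoothed left points indexed near
    ``k`` and smoothed right points indexed near ``k`` (windows proportional
    to each side's point count); the overall width is the mean over the
    central 60% of the spine points (k = 2..8 for m = 11).
    """
    ol = np.asarray(outline_left, dtype=float)
    orr = np.asarray(outline_right, dtype=float)
    m = len(spine)
    if len(ol) < 5 or len(orr) < 5:
        return float("nan")
    ols, orrs = _boxcar5(ol), _boxcar5(orr)
    edge = int(round(0.2 * (m - 1)))
    widths = []
    for k in range(edge, m - edge):
        wi = _width_window(len(ol), k, m)
        wj = _width_window(len(orr), k, m)
        d = np.linalg.norm(ols[wi][:, None, :] - orrs[wj][None, :, :], axis=-1)
        widths.append(float(d.min()))
    return float(np.mean(widths))


def compute_head_angle(spine: np.ndarray) -> float:
    """Signed head deflection angle in degrees, positive = left cast.

    A total-least-squares line is fit to the posterior 2/3 of the spine
    (points 0..6 of 11, tail first); of the anterior 1/5 (points 9..10) the
    point most distant from that line is selected.  The angle is
    ``atan2(d, l)`` where ``d`` is the point's signed perpendicular
    distance (positive to the LEFT of the tail-to-head axis) and ``l`` its
    along-axis distance beyond the head end of the fitted segment.
    """
    pts = np.asarray(spine, dtype=float)
    m = len(pts)
    n_post = max(2, int(round(2 * m / 3)))      # 7 of 11
    n_ant = max(1, int(round(m / 5)))           # 2 of 11
    fit = total_least_squares_line(pts[:n_post])
    if fit is None:
        return float("nan")
    c, u = fit
    # orient the axis tail -> head
    if np.dot(u, pts[-1] - pts[0]) < 0:
        u = -u
    n_left = np.array([-u[1], u[0]])  # 90 deg counter-clockwise from u
    proj_post = (pts[:n_post] - c) @ u
    head_end = float(proj_post.max())
    cand = pts[m - n_ant :]
    d = (cand - c) @ n_left
    ell = (cand - c) @ u - head_end
    pick = int(np.argmax(np.abs(d)))
    if abs(d[pick]) < 1e-12 and abs(ell[pick]) < 1e-12:
        return float("nan")
    return float(np.degrees(np.arctan2(d[pick], ell[pick])))


def compute_posture(track, T: float = 0.1, speed_span: str = "final") -> PostureSeries:
    """All five posture variables for one track.

    Variables that need geometry the track lacks (spine, outlines) are NaN
    throughout; speed/crabspeed are NaN within ``T/2`` of the track ends.
    """
    times = np.asarray(track.times, dtype=float)
    n = len(times)
    speed = np.full(n, np.nan)
    crab = np.full(n, np.nan)
    midline = np.full(n, np.nan)
    width = np.full(n, np.nan)
    head = np.full(n, np.nan)

    has_spine = track.spine is not None
    has_outline = track.outline_left is not None and track.outline_right is not None
    for i, t in enumerate(times):
        br = displacement_bracket(track, t, T)
        if br is not None:
            denom = br.span if speed_span == "final" else T
            speed[i] = br.chord_length / denom
            b = _body_axis(track, i)
            if b is not None:
                perp = br.chord - np.dot(br.chord, b) * b
                crab[i] = float(np.linalg.norm(perp)) / denom
        if has_spine:
            midline[i] = compute_midline(track.spine[i])
            head[i] = compute_head_angle(track.spine[i])
            if has_outline:
                width[i] = compute_width(
                    track.outline_left[i], track.outline_right[i], track.spine[i]
                )
    return PostureSeries(
        larva_id=track.larva_id,
        times=times,
        speed=speed,
        crabspeed=crab,
        midline=midline,
        width=width,
        head_angle=head,
    )
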