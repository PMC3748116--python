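"""Stimulus-aligned aggregation and statistical comparison of behaviors.

Action probabilities are percentages of animals performing an action in a
time window, computed over the animals whose track spans the whole window
(partially tracked animals are excluded from numerator and denominator).
Default windows are 5 s before stimulation and two consecutive 5 s windows
after it.  Proportions across two cohorts are compared on a 2x2
contingency table with Fisher's exact test when any cell is small (<= 5)
and the chi-squared test otherwise; continuous features (cast amplitude,
crawling speed, stride speed/frequency) use the two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_detection import EventRecord
from .io_formats import Experiment

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WINDOWS",
    "ActionProbability",
    "PopulationCurve",
    "spanning_animals",
    "action_probability",
    "build_contingency",
    "normalized_speed",
    "population_curve",
    "raster_matrix",
    "compare_proportions",
    "compare_continuous",
]

#: Default analysis windows in seconds relative to stimulus onset.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((-5.0, 0.0), (0.0, 5.0), (5.0, 10.0))


def spanning_animals(exp: Experiment, interval: tuple[float, float]) -> set[str]:
    """Larvae whose track covers the closed interval entirely.

    All probability denominators and per-animal feature samples are
    restricted to this set, so losing an animal mid-window (edge of arena,
    collision) cannot bias a window's statistics.
    """
    t0, t1 = interval
    if t1 < t0:
        raise ValueError("interval end precedes start")
    out = {
        lid for lid, tr in exp.tracks.items()
        if tr.times[0] <= t0 and tr.times[-1] >= t1
    }
    if not out:
        logger.warning("no animal spans [%.2f, %.2f] s", t0, t1)
    return out


@dataclass
class ActionProbability:
    """Percentage of spanning animals performing an action in a window."""

    percent: float
    n_performed: int
    n_spanning: int


def _matches_action(event_type: str, action: str) -> bool:
    # "cast" matches both cast_left and cast_right
    return event_type == action or event_type.startswith(action + "_")


def action_probability(
    events: Sequence[EventRecord],
    exp: Experiment,
    action: str,
    window: tuple[float, float],
) -> ActionProbability:
    """Percent of spanning animals with >= 1 ``action`` event starting in
    the half-open window [t0, t1) (absolute track time)."""
    t0, t1 = window
    spanning = spanning_animals(exp, window)
    if not spanning:
        return ActionProbability(float("nan"), 0, 0)
    performers = {
        ev.larva_id
        for ev in events
        if ev.larva_id in spanning and _matches_action(ev.type, action) and t0 <= ev.t_start < t1
    }
    pct = 100.0 * len(performers) / len(spanning)
    logger.info(
        "%s in [%.1f, %.1f): %d/%d animals (%.1f%%)",
        action, t0, t1, len(performers), len(spanning), pct,
    )
    return ActionProbability(pct, len(performers), len(spanning))


def build_contingency(
    n_performed_a: int, n_total_a: int, n_performed_b: int, n_total_b: int
) -> np.ndarray:
    """2x2 table: rows = cohorts A/B, columns = (performed, not performed)."""
    if not (0 <= n_performed_a <= n_total_a and 0 <= n_performed_b <= n_total_b):
        raise ValueError("performed counts must lie within totals")
    return np.array(
        [
            [n_performed_a, n_total_a - n_performed_a],
            [n_performed_b, n_total_b - n_performed_b],
        ]
    )


def normalized_speed(
    posture, onset: float, eps: float = 1e-9
) -> np.ndarray | None:
    """Per-animal speed normalized by its own pre-stimulus mean.

    Each time point's absolute crawling speed is divided by the animal's
    mean speed before ``onset``; values above 1 after stimulation indicate
    escape/avoidance crawl.  Returns None (animal excluded, logged) when
    the pre-stimulus mean is not positive (stationary animal).
    """
    speed = np.asarray(posture.speed, dtype=float)
    pre = speed[(posture.times < onset) & np.isfinite(speed)]
    if pre.size == 0 or pre.mean() <= eps:
        logger.info("larva %s: no usable pre-stimulus speed, excluded", posture.larva_id)
        return None
    return speed / pre.mean()


@dataclass
class PopulationCurve:
    """Mean +- s.e.m. of a per-animal series across a cohort."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "mean": self.mean, "sem": self.sem, "n": self.n})


def population_curve(
    series: Mapping[str, tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray,
) -> PopulationCurve:
    """Align per-animal series to a common grid and average across animals.

    Each animal contributes its nearest sample to every grid point (within
    one grid step; no interpolation, so no data is fabricated between
    frames).  ``sem`` is the sample standard deviation over animals divided
    by sqrt(n); NaN where fewer than 2 animals contribute.
    """
    grid = np.asarray(grid, dtype=float)
    step = float(np.median(np.diff(grid))) if len(grid) > 1 else np.inf
    stacked = np.full((len(series), len(grid)), np.nan)
    for row, (times, values) in enumerate(series.values()):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        idx = np.clip(np.searchsorted(times, grid), 1, len(times) - 1)
        nearer_left = (grid - times[idx - 1]) < (times[idx] - grid)
        nearest = np.where(nearer_left, idx - 1, idx)
        close = np.abs(times[nearest] - grid) <= step
        stacked[row, close] = values[nearest[close]]
    with np.errstate(invalid="ignore"):
        n = np.sum(np.isfinite(stacked), axis=0)
        mean = np.nanmean(np.where(n > 0, stacked, np.nan), axis=0)
        sd = np.full(len(grid), np.nan)
        enough = n >= 2
        sd[enough] = np.nanstd(stacked[:, enough], axis=0, ddof=1)
        sem = sd / np.sqrt(np.maximum(n, 1))
    return PopulationCurve(times=grid, mean=mean, sem=sem, n=n)


def raster_matrix(
    events: Sequence[EventRecord],
    exp: Experiment,
    onset: float,
    window: tuple[float, float] = (-15.0, 15.0),
    actions: Sequence[str] = ("cast", "roll", "hunch", "run"),
    bin_dt: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-animal binary rasters of action intervals, aligned to onset.

    For each action, rows are the spanning animals and columns time bins of
    one nominal frame period; a bin is 1 when an event interval of that
    action covers the bin center.  Binary by construction: overlapping
    events cannot double-set a bin.
    """
    w0, w1 = window
    if bin_dt is None:
        bin_dt = 1.0 / exp.frame_rate_nominal
    spanning = sorted(spanning_animals(exp, (onset + w0, onset + w1)))
    centers = np.arange(w0 + bin_dt / 2, w1, bin_dt)
    out: dict[str, pd.DataFrame] = {}
    for action in actions:
        mat = np.zeros((len(spanning), len(centers)), dtype=int)
        index = {lid: i for i, lid in enumerate(spanning)}
        for ev in events:
            if ev.larva_id not in index or not _matches_action(ev.type, action):
                continue
            covered = (centers >= ev.t_start - onset) & (centers <= ev.t_end - onset)
            mat[index[ev.larva_id], covered] = 1
        out[action] = pd.DataFrame(mat, index=spanning, columns=np.round(centers, 6))
    return out


def compare_proportions(
    table: np.ndarray, continuity: bool = True
) -> tuple[str, float]:
    """Compare two proportions on a 2x2 contingency table.

    Uses Fisher's exact test (two-sided) when any cell is <= 5, otherwise
    the chi-squared test (Yates continuity correction by default, the
    stock 2x2 behaviour of standard statistics environments).  Returns
    ``(test_name, p_value)``.  A table with a zero margin cannot
    discriminate; Fisher then yields p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t <= 5).any():
        return "fisher", float(stats.fisher_exact(t, alternative="two-sided")[1])
    res = stats.chi2_contingency(t, correction=continuity)
    return "chi2", float(res[1])


def compare_continuous(samples_a: Iterable[float], samples_b: Iterable[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples (both n <= 20), normal
    approximation with tie correction otherwise.  Identical samples give
    p = 1 by convention.
    """
    a = np.asarray(list(samples_a), dtype=float)
    b = np.asarray(list(samples_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
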