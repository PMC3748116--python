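"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by the most literal possible
method (per-sample state machines, exhaustive enumeration, closed forms)
so that the production implementations are checked against genuinely
independent computations.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def schmitt_reference(times, values, thr, polarity="peaks"):
    """Literal per-sample Schmitt state machine with fixpoint merging.

    Returns tuples (t_start, t_end, amplitude, polarity, truncated)
    sorted like the production detector's output.
    """
    times = list(map(float, times))
    vals = [0.0 if math.isnan(v) else float(v) for v in values]
    signs = {"peaks": [(1, "peak")], "wells": [(-1, "well")],
             "both": [(1, "peak"), (-1, "well")]}[polarity]
    results = []
    for sign, pol in signs:
        y = [sign * v for v in vals]
        raw = []
        state, start = "closed", None
        for i, v in enumerate(y):
            if state == "closed" and v >= thr.upper:
                state, start = "open", i
            elif state == "open" and v < thr.lower:
                raw.append([start, i - 1, False])
                state = "closed"
        if state == "open":
            raw.append([start, len(y) - 1, True])
        # merge any adjacent pair closer than the gap, repeat to fixpoint
        changed = True
        while changed:
            changed = False
            for k in range(len(raw) - 1):
                if times[raw[k + 1][0]] - times[raw[k][1]] < thr.gap:
                    raw[k] = [raw[k][0], raw[k + 1][1], raw[k + 1][2]]
                    del raw[k + 1]
                    changed = True
                    break
        for s, e, trunc in raw:
            if times[e] - times[s] >= thr.width:
                amp = max(abs(vals[j]) for j in range(s, e + 1))
                results.append((times[s], times[e], amp, pol, trunc))
    return sorted(results, key=lambda r: (r[0], r[3]))


def max_chord_bracket(positions, i, ia0, ib0):
    """Exhaustive maximal chord over all sub-brackets of [ia0, ib0] that
    still strictly bracket index ``i``."""
    best = 0.0
    for ia in range(ia0, i):
        for ib in range(i + 1, ib0 + 1):
            chord = float(np.linalg.norm(positions[ib] - positions[ia]))
            best = max(best, chord)
    return best


def boxcar5_reference(points):
    pts = np.asarray(points, dtype=float)
    out = np.empty_like(pts)
    for i in range(len(pts)):
        window = [pts[j] for j in range(max(0, i - 2), min(len(pts), i + 3))]
        out[i] = np.mean(window, axis=0)
    return out


def width_reference(outline_left, outline_right, spine):
    """Exhaustive evaluation of the morphological-width formula."""
    ol = boxcar5_reference(outline_left)
    orr = boxcar5_reference(outline_right)
    m = len(spine)
    n_l, n_r = len(ol), len(orr)
    edge = int(round(0.2 * (m - 1)))
    widths = []
    for k in range(edge, m - edge):
        best = math.inf
        for i in range(n_l):
            if not (n_l * (k - 1) / m < i < n_l * (k + 1) / m):
                continue
            for j in range(n_r):
                if not (n_r * (k - 1) / m < j < n_r * (k + 1) / m):
                    continue
                best = min(best, float(np.linalg.norm(ol[i] - orr[j])))
        assert math.isfinite(best), "oracle fixture must give nonempty windows"
        widths.append(best)
    return float(np.mean(widths))


def local_maxima_reference(values):
    """Indices i with values[i-1] < values[i] > values[i+1] (no plateaus)."""
    return [
        i for i in range(1, len(values) - 1)
        if values[i - 1] < values[i] > values[i + 1]
    ]


def fisher_exact_reference(table):
    """Two-sided Fisher p by direct hypergeometric enumeration: the sum of
    the probabilities of all tables (with the observed margins) no more
    likely than the observed one."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    def pmf(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )
    p_obs = pmf(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def ranksum_exact_reference(a, b):
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled ranks to sample A.  Requires tie-free samples."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    rank = {v: r + 1 for r, v in enumerate(pooled)}
    na = len(a)
    u_obs = sum(rank[v] for v in a) - na * (na + 1) / 2
    us = []
    for comb in combinations(range(1, len(pooled) + 1), na):
        us.append(sum(comb) - na * (na + 1) / 2)
    us = np.array(us, dtype=float)
    p = 2 * min(float((us <= u_obs).mean()), float((us >= u_obs).mean()))
    return min(1.0, p)


def random_bump_signal(rng, n=300, fps=15.0, n_bumps=None, amp_range=(0.2, 3.5),
                       dur_range=(0.05, 1.2), noise=0.15, signed=True):
    """Random test signal: Gaussian noise plus half-sine bumps of random
    sign, amplitude and duration (some straddling the thresholds)."""
    t = np.arange(n) / fps + rng.uniform(-0.01, 0.01, n)
    t = np.sort(t)
    y = rng.normal(0, noise, n)
    if n_bumps is None:
        n_bumps = int(rng.integers(0, 8))
    for _ in range(n_bumps):
        t0 = rng.uniform(t[0], t[-1])
        dur = rng.uniform(*dur_range)
        amp = rng.uniform(*amp_range) * (rng.choice([-1, 1]) if signed else 1)
        inside = (t >= t0) & (t <= t0 + dur)
        y[inside] += amp * np.sin(np.pi * (t[inside] - t0) / dur)
    return t, y
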