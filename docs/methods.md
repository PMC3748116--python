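# Methods

This note documents the models, parameter choices and numerical
conventions behind `larva-etho`, and what the bundled synthetic data can
and cannot establish.

## Input model

A track is a per-larva time series of tracked geometry at a nominal
15 fps: centroid `p(t)` (mm), an 11-point spine ordered tail→head, and
left/right outline point sequences (≥ 11 points per side). Timestamps
may be unevenly spaced (frame drops, tracker jitter); all algorithms
operate on the actual timestamps, never on frame indices. Tracks shorter
than 5 s, or whose maximum centroid excursion from the starting point is
below one body length (median midline length; 4 mm fallback for
centroid-only tracks), are rejected as debris or tracking fragments.
"Maximum excursion" rather than net start→end displacement is used so a
larva crawling back and forth is not mistaken for debris.

## Posture variables

**Displacement bracket.** Speed-like quantities at time `t` use the
chord `p(t_b) − p(t_a)` with `t_a, t_b` initialized to `t ± T/2`
(`T` = 0.1 s) snapped to the nearest samples and then moved inward one
sample per step — both ends together — while the chord length strictly
increases and both ends still bracket `t`. This is a fast heuristic for
the maximal chord in the window; it suppresses the cancellation that
direction reversals (rolls, casts) would cause in a plain two-point
difference. Within T/2 of the track ends the value is missing (NaN).

**Speed** is the final chord length divided by the final bracket span
(`t_b − t_a`); dividing by the fixed `T` instead is available as
`span="fixed"`. The final-span convention is the default because it is
dimensionally consistent for shrunk brackets.

**Crabspeed** is the magnitude of the same chord's component
perpendicular to the body axis `b(t)`, divided by the same span, so
crabspeed ≤ speed pointwise by construction. `b(t)` is the direction of
a total-least-squares line through the outline points of the frame
nearest `t` (spine points when outlines are absent — the same axis to
first order).

**Midline** is the summed Euclidean length of the spine polyline.
**Width** boxcar-averages each outline side over 5 points, takes for
each spine point `k` the minimum distance between left points indexed in
`(n_L(k−1)/m, n_L(k+1)/m)` and right points indexed likewise (clamped to
at least one index per side at the tail/head edges), and averages the
central 60% of spine points (k = 2..8 of 11).

**Head angle** fits a total-least-squares line to the posterior 2/3 of
the spine (points 0..6), selects among the anterior 1/5 (points 9..10)
the one most distant from that line, and reports
`atan2(d, ℓ)` in degrees, where `d` is the signed perpendicular distance
and `ℓ` the along-axis distance beyond the head end of the fitted
segment. The sign convention is **positive = left cast** (the signed
distance is taken positive to the left of the tail→head axis), so peaks
in the series are left casts and wells right casts — the convention all
downstream detection uses. The distance→angle conversion is a package
convention: it is monotone in `d`, zero for a straight animal, and gives
45° when the head tip sits one unit out and one unit forward.

## Event detection (non-oscillating signals)

The extended Schmitt trigger uses four thresholds per action: upper and
lower amplitude, width, gap. On discrete samples, an event opens at the
first sample with |x| ≥ upper and closes after the last sample with
|x| ≥ lower; boundaries sit on samples (no sub-sample interpolation —
at 15 fps that is the data's native resolution). A single event shorter
than the width threshold is discarded; two or more same-polarity events
separated by less than the gap threshold merge (left-to-right,
transitively) and survive if the merged span reaches the width
threshold. Event amplitude is the maximum |x| over the event interval,
gaps included. Events still open at the track end are closed there and
flagged truncated.

Action mapping: rolls = peaks in crabspeed; casts = peaks (left) and
wells (right) in head angle, on the raw signal since it is naturally
zero-centred; hunches = wells in the midline referenced to a per-animal
running median over 5 s — a window chosen well above the 0.2 s hunch
width threshold so brief retractions survive while slow length drift
(peristaltic stretching, growth of the tracked contour) is removed.
Tracks shorter than the baseline window fall back to the per-track
median. Cast and hunch candidates lying fully inside a roll interval are
discarded: rolling corrupts the projected posture geometry, and richer
multi-variable disambiguation rules are out of scope.

A note on monotonicity: a larger gap threshold can only merge more, so
it never increases the event count. Raising the upper amplitude
threshold never increases the count *in the absence of merging*; with
merging, deleting a middle burst can split one merged event into two, so
the property is only guaranteed in the no-merge regime (and is tested
there).

**Threshold tuning** mirrors the iterative manual procedure: a grid of
candidate threshold sets is scanned in order and the first set achieving
a false detection rate < 5% and a false negative rate < 15% against
expert labels is returned; if none qualifies, the set minimizing
FDR + FNR is returned flagged non-compliant. At least 30 positive
labeled instances are required; negative instances are counted as
label-free gaps at least as long as the median labeled duration (the
original labeling protocol's negative unit is not recoverable, so this
package defines one).

## Strides and runs (the oscillating speed signal)

Stride peaks are strict local maxima of the speed trace (plateaus
resolve to their midpoint, deterministically); peak boundaries are the
flanking local minima, with track ends counting as minima. A peak is
good if its amplitude exceeds the 0.6 mm/s floor **and** 3/10 of the
mean amplitude over *all* detected peaks of the animal's trace
(sub-floor peaks are included in that mean; switchable via the peak
list handed to the classifier). Good peaks chain into runs while
consecutive peak positions are ≤ 2 s apart and no roll or cast starts
between them; bad peaks between two good peaks do not break adjacency
(the termination rules are only the gap and the interrupting actions).
Chains of ≥ 3 peaks become runs bounded by the first peak's left bound
and the last peak's right bound. Two refinements keep runs and
interrupting events disjoint: peaks positioned inside an interrupting
event interval are not strides, and run boundaries are clamped so an
interrupting event interval never lies inside a run.

Run features: duration; mean maximum stride speed (arithmetic mean of
member peak amplitudes, exact); stride frequency from a Lomb-Scargle
periodogram of the run's (mean-subtracted) speed segment, which remains
valid for unevenly sampled series. The frequency grid spans 0.2–5 Hz —
bracketing larval stride rates, below the 7.5 Hz Nyquist limit of 15 fps
— at a resolution of `1/(4 × segment duration)` (oversampling 4). The
estimate is flagged unreliable for segments shorter than two periods at
the lowest grid frequency or when no spectral peak stands ≥ 3× above the
median periodogram power; `n_strides / duration` serves as an
independent consistency diagnostic. The periodogram is
`scipy.signal.lombscargle`.

## Windowed statistics

All per-window statistics are computed over the animals whose track
spans the entire window (animals lost to the arena edge or collisions
mid-window are excluded from numerator and denominator alike). An animal
"performed" an action in a window when at least one event of that type
*starts* in the half-open window — a convention that assigns
boundary-straddling events unambiguously. Default windows: [−5, 0),
[0, 5), [5, 10) s around stimulus onset.

Proportions across cohorts are compared on 2×2 tables (performed / not ×
cohort): Fisher's exact test when any cell is ≤ 5, otherwise chi-squared
with Yates continuity correction (the stock 2×2 default of standard
statistics environments; switchable). Continuous features use the
two-sided Wilcoxon rank-sum test — exact enumeration for tie-free
samples up to n = 20, normal approximation with tie correction beyond.
P-values are reported per comparison without multiple-testing
correction, matching common practice for these screens; apply a
correction downstream if many comparisons are made.

Normalized crawling speed divides each animal's speed trace by its own
pre-stimulus mean (animals with no usable pre-stimulus crawl are
excluded and logged), so values above 1 after onset indicate
escape/avoidance crawl regardless of baseline vigor. Population curves
average per-animal series aligned to a common grid by nearest sample
(within one grid step; no interpolation, so no data is fabricated
between frames), reporting mean ± s.e.m. and per-point n. Raster
matrices are per-animal binary timelines, one bin per nominal frame
period, set where an event interval covers the bin centre.

## Synthetic cohorts

The generator emulates the study conditions at cohort scale: 15 fps
sampling with small timestamp jitter (±3 ms) and 1% frame drops, 30 s
baseline + 15 s post-stimulus, body length ~N(4, 0.3) mm, width
~N(1, 0.08) mm, stride frequency ~N(1, 0.15) Hz, stride peak speed
~N(1.2, 0.15) mm/s. The default preset schedules rolls for 35% of
animals shortly after onset with amplitudes ~N(4.66, 0.8) mm/s truncated
to ≤ 8 mm/s, hunches for 30% at onset, exploratory casts throughout
(~2 per animal), and a post-stimulus escape-crawl speed factor of 1.5.
Casts and hunches have no published amplitude/duration distributions;
the defaults (casts ~N(48, 8)° clipped to [36, 70]°, 0.5–1.2 s; hunches
~N(0.33, 0.05) mm depth clipped to [0.26, 0.5] mm, 0.45–0.9 s) are
plausible clearly-performed actions sized so that an event spans enough
frames above its lower threshold to be resolvable at all at 15 fps — an
action narrower than about two frame periods above the lower threshold
is undetectable at this frame rate regardless of thresholds. Other
presets: `noisy` (3× measurement noise), `adversarial` (heavy noise and
amplitudes straddling the thresholds, for exercising the tuning loop's
non-compliant path), `noxious-heat`, `vibration` (hunch→cast sequence at
onset), `air-current`.

Signals mode emits the five posture variables directly: speed is a
rectified sinusoid at the stride frequency (escape-scaled after onset,
combined with roll laterals as a vector magnitude), crabspeed carries
half-sine roll bursts, head angle half-sine cast excursions (positive =
left), midline half-sine hunch dips, everything plus Gaussian noise
(defaults: 0.05 mm/s speed, 0.12 mm/s crabspeed, 3° head angle, 0.03 mm
midline, 0.02 mm width).

Geometry mode realizes the same schedule as an analytic worm: a straight
trunk of the scheduled midline length advancing along a slowly wandering
heading at the stride-oscillating speed; casts bend the two anterior
spine points by twice the target head angle about the trunk axis (the
head-angle metric's `atan2(d, ℓ)` geometry halves the bend back, so the
scheduled amplitude is recovered exactly up to sampling); hunches
shorten the spine symmetrically; rolls translate the centroid
perpendicular to the body axis; outlines offset the spine by a tapered
half-width profile whose taper is confined to the tip points so the
trunk is at full width wherever the width metric samples it. Round-trip
recovery on this worm is within 2% for width, 3° for cast angle and
0.05 Hz for stride frequency at default noise.

What the generator does **not** model: real peristaltic body-shape
dynamics (speed oscillation is imposed, not emergent from segment
contraction), body bending during runs and turns (the trunk is rigid),
larva–larva contact and the resulting track losses, tracker segmentation
artifacts, and correlated (non-Gaussian) measurement noise. Detector
error rates measured on the benchmark therefore establish correctness of
the detection algorithms under the stated signal model — not expected
performance on real video-derived tracks, where the multi-variable
disambiguation the original screening software applied would matter
more.

**Benchmarking** matches detections to ground truth greedily in
start-time order, requiring the same larva and type and a temporal
overlap of at least half the shorter interval; FDR = FP/(TP+FP),
FNR = FN/(TP+FN). The 0.5-overlap criterion is a package convention (the
original expert-comparison protocol is not recoverable). On the default
200-larva benchmark the roll, cast and hunch detectors at the published
default thresholds sit well inside the tuning criteria (FDR ≤ 5%,
FNR ≤ 15%); `scripts/acceptance.py` recomputes this end to end.

## Numerical conventions and edge cases

* Missing values are NaN throughout; detectors treat NaN samples as
  baseline (outside any event).
* All tie-breaks are deterministic: plateau peaks take the midpoint,
  the anterior point with the larger |d| wins head-angle selection,
  grid search returns the first qualifying threshold set.
* Degenerate geometry (all-coincident spine points, zero-extent fits)
  yields missing values, with a warning where it indicates data trouble.
* Event-interval counting is half-open on starts (`t0 ≤ t_start < t1`)
  everywhere a window is involved.
* All randomness in the generator flows from one integer seed;
  identical seeds give bit-identical cohorts.

## Problem sizes

The bundled validation runs at desk scale by design: the detector
benchmark uses 200 simulated animals (~675 frames each, signals mode);
trigger-oracle equivalence uses 1000 random signals of ~300 samples;
geometry round trips use 4 animals at 25 s, where the full posture
pipeline (TLS fits and width minimization per frame) dominates the cost.
These sizes give stable rate estimates (hundreds of events per detector)
while keeping the whole suite under a minute.
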