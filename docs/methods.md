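# Methods

This note documents the models, conventions and numerical choices behind
`nestflick`, and what the synthetic benchmarks do and do not demonstrate.

## Motion model

Motion is quantified purely by frame differencing: for consecutive frames
f_t−1, f_t the per-pixel absolute luminance difference |f_t − f_t−1| is
computed (color input is first collapsed to Rec. 601 luma), then averaged
over each test square. We use the **mean** absolute pixel difference as
the square-level Δlum statistic (a `sum` reducer is available): the mean
keeps the square value on the same 0–255 scale as pixels, so the 2.0
event threshold is independent of camera resolution and square size.
Differences are unsigned — only the magnitude of posture change matters.
No registration, stabilization or optical flow is attempted; the pipeline
assumes a fixed camera and a static background, which matched the field
recordings this design follows and holds exactly for the generator.

Difference frames are indexed by the *later* frame: motion first visible
in frame t is reported at onset t. `detect_events` on a bare array uses
array indexing; the pipeline passes `first_frame_index=1`.

## Test grids

Squares are 1.5 cm — the image footprint of one surface bee — with
0-based (row, col) indices, row 0 at the top, and half-open pixel
intervals (a boundary pixel belongs to the square whose lower edge it
sits on). Trailing pixels that do not fill a whole square are outside the
grid. Physical extents (`unit_len_cm`) are informational only and never
enter computation. Exclusion masks (mouth zone, off-nest regions) can be
given as explicit square lists or as pixel polygons; a square is excluded
if its center falls inside the polygon. The relF denominator is the
number of *active* (non-masked) squares passed to `relf_metrics`, not the
grid bounding box, because real nests do not fill their grid.

## Event model and interval filter

A flicker is a run of 1–3 consecutive difference frames with Δlum
strictly greater than the threshold (default 2.0). Runs of 4+ frames are
sustained motion — fanning, walking, dancing — and produce *no* event;
this single rule is what separates flickers from other abdomen-flipping
behavior. The observation that natural flickers repeat after more than
one second is implemented as a refractory window (default 1.0 s): events
whose onsets are closer are merged into the earlier event (peak and
summed Δlum accumulate; the onset and duration of the earlier event are
kept). It is a merging rule, not a requirement that events recur, so
isolated flickers survive. The duration bound is defined in frames with
the frame rate recorded in config; at 50 fps 3 frames = 60 ms, at 25 fps
120 ms.

Shimmering waves saturate the difference image across many squares at
once, making flicker detection impossible while they pass. Since manual
wave marking cannot be reproduced, episodes are detected automatically:
frames where the fraction of simultaneously supra-threshold active
squares reaches `frac_threshold` (default 0.15), grouped into maximal
runs of at least `min_len_frames` (default 3). Episode intervals are
half-open (`end_frame` exclusive) so the end > start invariant also holds
for short episodes. Events overlapping any episode, and events in masked
squares, are removed by `filter_events` (idempotent).

## Trigger sites and cohorts

Each registered wave contributes trigger activity 1.0 to its source
square and its 8 Moore neighbours — the "trigger cohort" of bees around
the initiator — clipped at the nest border (no wrapping, no
renormalization, which preserves additivity of pooling). Activities are
pooled per experimental phase and scaled to the per-phase maximum for
rendering (an all-zero map stays zero). The ts/nts partition is
activity > 0 vs the rest of the active squares, recomputed per phase;
scaling does not affect it.

## Rate/intensity statistics

Rates are kept in Hz internally (events per minute only for display).
Intensity fI = Σ event Δlum / t_ref, where t_ref is the analyzed duration
of the phase. Rates are binned into 30 half-open classes of width
0.03 s⁻¹; rates beyond the top class are capped into class 29 with a
warning. Squares with zero rate are excluded from the class compilation
by default (they carry no flickering) but remain in the records table so
occupancy (relF) stays consistent. Per-class SEM is the sample standard
deviation over √n, reported as 0 for n = 1.

The class-mean rate-intensity curve is fitted as y = a·e^(b·x) by
ordinary least squares of ln y on x (class midpoints); a = e^intercept,
b = slope, and R² is that of the log-linear regression. Non-positive
means are dropped with a warning; noiseless curve data is recovered
exactly, and a constant y gives b = 0 with R² defined as 1 (zero total
variance is a perfect fit). Fits use unweighted class means, matching the
compile-then-fit order of the statistics; a Spearman rank correlation
(mid-rank ties, two-sided P, via scipy) tests the rate-intensity
association on the per-square records.

The cohort contrast uses the per-class signed difference
ΔfI = mean fI_ts − mean fI_nts over classes populated by both cohorts;
zero differences join neither sign group. The positive/negative counts
are tested with χ² = (n₊ − n₋)²/(n₊ + n₋), df = 1, no continuity
correction (P from the χ² survival function).

## Synthetic scenes

The generator's defaults encode the study conditions the analysis
assumes: 50 fps, 1.5 cm squares (8–12 px), flicker amplitudes ~8 Δlum
units (sd 1.5) with durations 1–3 frames (probabilities 0.5/0.3/0.2),
per-square rates of order 0.05–0.4 events/s, a minimum inter-event gap of
1.2 s, and additive Gaussian sensor noise of 0.5 luminance units.

Flicker onsets follow a renewal process: inter-event times are
min_gap + Exponential(1/rate − min_gap), so intervals always exceed the
gap and the long-run rate converges to min(rate, 1/min_gap). The natural
inter-flicker distribution is only known to exceed one second; the
exponential excess is an assumption. When frame quantization would place
an onset on an inadmissible frame, it moves to the first admissible one
(the continuous interval is always legal by construction).

Bees are static filled ellipses (semi-axes 0.40/0.30 of the square side,
≈ 38% area). An event of duration d toggles the ellipse between two
luminance postures on each of its d frames — a sustained step would show
on only two difference frames, so toggling is the only way a d-frame
event yields exactly d supra-threshold difference frames. Odd-duration
events therefore leave the bee in the flipped posture, as a real abdomen
flip does; the toggle direction is chosen to stay inside the 8-bit range
and any saturation is flagged (`GroundTruth.clipped`). The pixel step is
the integer nearest amplitude/area-fraction, and ground-truth amplitudes
are re-recorded as the *realized* per-square mean |Δlum| after this
quantization, so oracles compare against exactly what is rendered.
Waves expand at constant speed in Chebyshev distance with Bernoulli
participation per reached square (single-frame flips); mouth-zone squares
toggle on every frame. Frames are 8-bit with saturation clipping; noise
is added per pixel per frame before rounding.

Scenes are deterministic: one `SeedSequence` per config spawns separate
event and noise streams, so wave-only scenes have seed-independent ground
truth while pixel noise varies.

What the generator does **not** emulate: bee locomotion and crowding,
photometric drift and flicker of daylight, 3-D curtain geometry and
occlusion, camera shake, and overlapping events of different kinds on one
square (schedules overwrite; the benchmarks keep kinds on disjoint
squares). Perfect recall on synthetic scenes therefore demonstrates the
correctness of the detector's logic under its stated assumptions, not its
robustness to unmodelled field conditions.

## Benchmark problem sizes

The detection benchmark renders the smaller field nest's grid (48 × 73
squares at 8 px) for 3000 frames (60 s at 50 fps) with ~500 ground-truth
flickers, once noise-free and once with sd 0.5 noise. The cohort-contrast
benchmark is evaluated at the event level (the statistics consume event
tables, so pixel rendering would add nothing): 100 replicates of a
30 × 30 nest with 225 ts and 225 nts squares (amplitudes 8 vs 5) over
120 s. The end-to-end pipeline tests use a 10 × 12 nest for 800 frames.

## Known limitations

* Square-level Δlum from real footage depends on unmodelled factors
  (contrast, exposure); the 2.0 threshold is exposed in config and should
  be re-calibrated per recording.
* The refractory merge keeps the earlier event's duration, so a merged
  pair is counted once with the first event's length.
* Automated shimmer masking needs the wave to cover `frac_threshold` of
  the active squares for `min_len_frames`; small or slow waves below that
  footprint are not masked and their flips are counted as flickers.
* Trigger registries treat every listed trigger event as one entry;
  parental and daughter waves are not distinguished beyond their ids.
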