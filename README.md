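# nestflick

Grid-based video quantification of **flickering** and **shimmering** in
Giant Honey Bee (*Apis dorsata*) nests.

Giant Honey Bees defend their open nests with *shimmering*: wave-like
cascades of dorso-ventral abdomen flips sweeping across the curtain of
surface bees. Under quiescent conditions the same bees show *flickering* —
brief, seemingly stochastic abdomen flips of single individuals. Whether
flickering is organized around the **trigger sites** (*ts*) from which
shimmering waves are launched, and how it responds to arousal, is a
question about the colony's intrinsic information system. Answering it
requires turning hours of nest video into per-bee event statistics.

`nestflick` implements that measurement pipeline for behavioral
ecologists and collective-behavior researchers:

1. **Motion fields** — consecutive frames are subtracted into per-pixel
   absolute luminance differences Δlum ∈ [0, 255] (0 = motionless), then
   aggregated over a lattice of bee-sized *test squares* (1.5 cm side).
2. **Flicker events** — per square, maximal runs of difference frames with
   Δlum > 2.0 lasting at most 3 frames (60 ms at 50 fps) are flickers;
   longer runs are other motion (fanning, walking) and are rejected.
   Events repeating within 1 s are merged (refractory window), frames
   swept by shimmering waves and the high-traffic mouth zone are masked.
3. **Trigger-site maps** — each registered wave assigns trigger activity
   1.0 to its source square and the 8 squares around it; pooled per
   experimental phase and scaled to the per-phase maximum. Squares with
   non-zero pooled activity form the *ts* cohort, the rest are *nts*.
4. **Cohort statistics** — per square: rate (events/s) and intensity
   *fI* = Σ Δlum / t_ref. Rates are binned into 30 classes of 0.03 s⁻¹;
   per-class intensity means ± SEM per cohort are summarized by
   exponential fits *y = a·e^(b·x)* (log-linear least squares), the
   rate-intensity association by Spearman correlation, and the cohort
   contrast by the sign pattern of Δ*fI* = *fI*ₜₛ − *fI*ₙₜₛ tested with a
   df = 1 χ² = (n₊ − n₋)²/(n₊ + n₋) against equal expectation.
5. **Synthetic nests** — since no field footage is public, a generator
   renders 8-bit nest videos with exact ground truth: renewal-process
   flickers (> 1 s repeat interval), radial waves, sustained mouth-zone
   motion and Gaussian sensor noise, so every stage is testable.

## Worked example

```python
import nestflick as nf

cfg = nf.SceneConfig(
    grid_rows=10, grid_cols=12, n_frames=1500, square_px=8, fps=50.0,
    noise_sd=0.5,
    cohorts=(
        nf.CohortSpec(squares=tuple((r, c) for r in (2, 3, 4) for c in (2, 3, 4)),
                      flicker_rate=0.2, amplitude_mean=8.0),
        nf.CohortSpec(squares=tuple((r, c) for r in (6, 7, 8) for c in (6, 8, 10)),
                      flicker_rate=0.2, amplitude_mean=5.0),
    ),
    seed=7)
series, truth = nf.render_square_series(cfg)          # 30 s of 50 fps video
detected = nf.detect_events_grid(series, nf.EventFilterConfig())
m = nf.match_events(truth.flickers(), detected)
print(f"{m.n_truth} ground-truth flickers, {m.n_detected} detected "
      f"(recall {m.recall:.2f}, precision {m.precision:.2f})")

registry = nf.TriggerRegistry((nf.TriggerEntry("w0", "all", (3, 3)),))
pooled = nf.pool_trigger_activity(registry, (10, 12))
part = nf.partition_cohorts(pooled, {(r, c) for r in range(10) for c in range(12)})
records = nf.build_rate_intensity_table(detected, part, t_ref=cfg.duration_s)
comp = nf.cohort_difference(nf.bin_rate_classes(records))
print(f"ts cohort: {len(part.ts_squares)} squares, nts: {len(part.nts_squares)} squares")
print(f"delta_fI sign counts: {comp.n_positive} positive, {comp.n_negative} negative "
      f"(chi2 = {comp.chi2:.2f}, P = {comp.p_value:.3f})")
```

prints

```
97 ground-truth flickers, 96 detected (recall 0.99, precision 1.00)
ts cohort: 9 squares, nts: 111 squares
delta_fI sign counts: 3 positive, 0 negative (chi2 = 3.00, P = 0.083)
```

The scene plants two flicker cohorts (event amplitudes 8 vs 5 Δlum units)
on a 10 × 12 grid; one event drew an amplitude below the 2.0 detection
threshold and is — correctly — not recovered. The single registered wave
at square (3, 3) defines a 9-square trigger site; in every populated rate
class the high-amplitude cohort is the more intense one (3 positive signs,
no negative), though three classes are too few for χ² significance.

## Command line

```
nestflick simulate  --config run.yaml --out sim/        # render + ground truth
nestflick detect    --frames sim/frames --out det/      # events + episodes
nestflick map-triggers --registry reg.csv --rows 48 --cols 73 --out maps/
nestflick analyze   --events det/events.csv --registry reg.csv \
                    --rows 48 --cols 73 --t-ref 60 --out stats/
nestflick run-all   --config run.yaml                   # one-shot pipeline
```

Frames are numbered grayscale PNGs or a multi-page TIFF; tables are CSV;
summaries JSON; trigger maps additionally as white→red heatmap PNGs.

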