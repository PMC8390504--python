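# embryoquant

Quantitative image analysis for two-compartment embryoids — stem-cell
aggregates that fuse an epiblast-like (EPI) compartment with a
trophoblast stem cell (TS) compartment and polarize expression of the
mesendoderm marker T/Bra (Brachyury). Given three-channel 2D frames
(brightfield for the whole structure, GFP for the TS compartment,
mCherry for the T/Bra reporter), the package measures, per embryoid and
time point:

- **Compartment areas** (µm²): total, TS, EPI = brightfield \ GFP,
  reporter = mCherry ∩ EPI, anterior EPI = EPI \ mCherry.
- **Reporter positivity**: positive iff the background-normalized mean
  reporter intensity is ≥ 1.3 (signal ≥ 30% above background) and the
  reporter area is ≥ 1500 µm².
- **Coverage index**: reporter area / EPI area ∈ [0, 1].
- **Minimum Feret diameter**: smallest caliper width of the aggregate,
  by rotating calipers on the convex hull.
- **Axial morphometry**: a chain of maximal inscribed circles is fitted
  into the (TS-subtracted) object; the axial length is the length of the
  path connecting the circle centers and the **elongation index** is
  axial length / diameter of the largest inscribed circle — 0 for round
  objects, (L − W)/W for a straight capsule of length L and width W.
- **Onset of expression**: for a time-lapse series, the earliest frame at
  which the positivity criterion holds (optionally for several
  consecutive frames), plus cohort summaries (fraction positive at a
  time point).

Because such pipelines are normally validated only by eye, the package
ships a first-class synthetic embryoid generator
(`embryoquant.synthetic`) that renders multi-channel frames, curved
capsule shapes, and time-lapse ramps with exact ground truth (masks,
areas, coverage, onset time, centerline length), so every stage is
testable without microscopy data. See `docs/methods.md` for the
measurement model and numerical choices.

## Worked example

```python
import embryoquant as eq

# render a synthetic embryoid: 40% reporter coverage, 2x background
# reporter intensity, 5% Gaussian noise, 1.3 µm/px
params = eq.GeneratorParams(seed=7, reporter_coverage=0.4,
                            reporter_intensity_factor=2.0, noise_sd=5.0)
image, truth = eq.generate_embryoid_image(params)

meas = eq.measure_frame(image)
print(f"EPI area: {meas.areas.area_epi:.0f} um^2 (truth {truth.area_epi_um2:.0f})")
print(f"coverage: {meas.coverage_index:.3f} (truth {truth.coverage:.3f})")
print(f"ratio: {meas.normalized_mean_intensity:.2f}  positive: {meas.positive}")
```

prints

```
EPI area: 19885 um^2 (truth 19885)
coverage: 0.398 (truth 0.398)
ratio: 2.00  positive: True
```

— the EPI compartment of the default ellipse (~180 × 140 µm) is
recovered to the pixel, the measured coverage matches the rendered
40% cap, and the embryoid is called reporter-positive because its
normalized intensity (2.0 ≥ 1.3) and reporter area (~7900 µm² ≥ 1500)
both clear the criterion.

Shape scoring on a known geometry:

```python
import numpy as np
mask, _ = eq.generate_capsule_mask(200.0, 50.0, curvature=0.0, pixel_size=1.0)
res = eq.elongation_index(eq.fit_circle_chain(mask))
print(f"axial {res.axial_length_um:.0f} um, index {res.elongation_index:.2f}")
# -> axial 159 um, index 3.05   (analytic (L-W)/W = 3.0)
```

## Command line

```sh
embryoquant generate --out-dir frames --n 10 --seed 1      # synthetic TIFFs + truth
embryoquant measure frames/embryoid_000.tif                # one frame
embryoquant batch frames --out-dir results                 # results.csv + config hash
embryoquant generate --out-dir tl --timelapse --onset 110  # series + manifest.csv
embryoquant series tl/manifest.csv --persistence 2         # onset detection
embryoquant report results/results.csv --at-time 120       # cohort summary
```

Frames are multi-page TIFFs (brightfield, GFP, mCherry), time-lapse
series are described by a manifest CSV (`frame_path,time_h`), and results
are tidy CSVs (one row per embryoid-timepoint) written next to the YAML
config and its hash — re-running with the same inputs and config is
byte-identical.

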