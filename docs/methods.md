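# Methods

`embryoquant` quantifies two-compartment embryoids (an epiblast-like EPI
aggregate fused to a trophoblast-stem-cell TS aggregate) from
three-channel 2D microscopy frames: brightfield outlines the whole
structure, GFP labels the TS compartment, and mCherry reports T/Bra
(Brachyury) expression. This note records the measurement model, the
numerical choices behind it, and what the synthetic validation data can
and cannot show.

## Measurement model

**Segmentation.** Each channel is reduced to at most one object:
threshold (Otsu by default, or a fixed value), keep the largest
8-connected component, fill holes, and discard objects below a physical
floor (default 1500 µm², the same floor the positivity criterion uses).
8-connectivity with hole filling is deliberate: embryoid lumens would
otherwise punch holes into every area measurement. Brightfield polarity
is configurable (`bright-object`/`dark-object`) because real brightfield
objects are often darker than their surround while the synthetic data
renders them brighter.

**Compartment areas.** All areas are set-difference pixel counts scaled
by `pixel_size²`:

- EPI = brightfield \ GFP
- reporter = mCherry ∩ EPI
- anterior EPI = EPI \ mCherry

Mask arithmetic rather than scalar subtraction keeps every area
non-negative under partial overlap and reduces to plain subtraction when
the objects nest (the usual situation). Intersecting the reporter with
the EPI also bounds the coverage index

    coverage = |mCherry ∩ EPI| / |EPI|

to [0, 1] even when the reporter object bleeds over the TS compartment.

**Reporter positivity.** An embryoid is positive when the
background-normalized mean reporter intensity is at least 1.3 (signal
≥ 30% above background) *and* the reporter compartment covers at least
1500 µm². Both boundaries are inclusive; "signal" is the mean intensity
over the reporter object, consistent with reporting background-normalized
mean intensities. The background is the mean intensity outside all
segmented objects dilated by a 10 px margin, re-estimated per frame so
that illumination drift in a time-lapse does not propagate.

Two pipeline details matter for faithfulness:

- The mCherry object is segmented **without** the area floor — the
  1500 µm² floor belongs to the positivity call, while the coverage
  index should see small expression domains too.
- A **colocalization guard** rejects a reporter object when less than
  half of it lies inside the brightfield object. Thresholding a
  signal-free fluorescence channel splits the noise roughly in half and
  the above-threshold half percolates into one sprawling component; such
  an object covers mostly background and is discarded (flag
  `reporter-outside-object`) instead of polluting the coverage index.
  As an alternative, `measure_frame(mch_background_offset=True)`
  thresholds mCherry at `1.3 × background` (a background-offset
  threshold), which cannot produce noise objects at realistic noise
  levels but also cannot detect reporter signal below 30% above
  background.

**Minimum Feret diameter.** The smallest caliper width of the
brightfield object, computed on the convex hull of true-pixel centers:
the minimum width is attained with a hull edge flush against one jaw, so
minimizing, over hull edges, the farthest vertex distance from the edge
line is exact. One pixel is added before scaling to physical units
because pixel centers under-span the physical pixel extent by half a
pixel on each side; a single-pixel object therefore measures one pixel
wide, and a 100 × 40 px axis-aligned rectangle measures exactly 40.

**Axial morphometry.** Shape scoring follows the inscribed-circle
construction: fit a chain of maximal inscribed circles, connect their
centers, and report

    elongation index = axial length / diameter of the largest inscribed circle

which is 0 for a disk and (L − W)/W for a straight capsule of
end-to-end length L and width W. For elongation scoring the TS
compartment is first removed (brightfield \ GFP, largest remnant kept),
since the attached TS aggregate would otherwise register as spurious
axial length.

The circle-placement procedure works on the Euclidean distance transform
(EDT), computed with the image border treated as background:

1. Circle 1 is a maximal inscribed circle. Its radius is the EDT
   maximum; its center is chosen on the near-maximal plateau (within
   1 px of the maximum) at the point nearest the plateau centroid. On
   elongated shapes the EDT maximum is a ridge plateau whose exact
   arg-max position is an artifact of rasterization; seeding mid-plateau
   makes the chain grow symmetrically toward both ends and keeps the
   result stable under rotation. (The standalone `max_inscribed_circle`
   function uses the exact arg-max with row/column tie-breaking, which
   is the right contract for a single-circle query.)
2. Each subsequent center maximizes the EDT of the *not-yet-covered*
   region — the point around which the largest fresh disk fits. This is
   the step that keeps chains on the object's midline: thin leftover
   slivers along an already-covered boundary have tiny uncovered-EDT and
   never attract circles, whereas a naive arg-max of the original EDT
   over uncovered pixels places small off-axis circles in those slivers
   and zigzags the center path (30–100% axial-length inflation on
   rotated capsules in our measurements). Near-ties (within 1 px) are
   resolved toward the candidate farthest from the placed centers, so
   chains march end-to-end. Radii are always measured against the
   original mask boundary, so the chain reports the true local
   half-width.
3. Iteration stops when the largest fresh disk falls below
   `stop_ratio × r₁` (default 0.5), when the placed disks cover
   `coverage_stop` (default 0.95) of the object, or at `max_circles`
   (default 50). The 0.5 stop ratio is what separates genuine side
   lobes (which admit fresh disks comparable to the local width) from
   tangency-lens gaps between consecutive chain disks (fresh radii
   ≤ ~0.45 r₁); lowering it admits lens circles and destabilizes the
   path, raising it truncates genuinely lobed shapes.
4. Centers are ordered into a path by nearest-neighbor chaining starting
   from the most eccentric center (greatest distance to any other);
   axial length is the sum of consecutive center distances. A single
   circle has axial length 0.

Measured behavior with the defaults: disks of radius ≥ 20 px score
< 0.05; a 200 × 50 µm capsule scores 2.9–3.1 across rotations of
0–90° (variation ≈ 6%); a quarter-turn bent capsule's axial length is
within ~3% of the skeleton-geodesic diameter of the same mask; the index
increases strictly in capsule length over 100–300 µm. Note the
degenerate end of that range: a 100 × 50 µm capsule (2:1 aspect) is
covered by its first circle up to sub-threshold crescents and scores 0 —
the construction does not resolve elongation below roughly 3:1.

**Onset detection.** Each time-lapse frame is measured independently;
the onset is the earliest frame time whose positivity call is true for
`persistence` consecutive frames (default 1; 2 recommended for noisy
data). Onset is reported as the frame time, never interpolated, matching
2 h acquisition resolution. Raising either the intensity threshold or
the persistence can only delay the detected onset.

## Synthetic ground truth

The generator renders what the measurement consumes: an EPI ellipse and
an attached TS disk at `foreground_level` in brightfield, the TS disk
alone in GFP, and a polarized reporter domain at `factor × background`
in mCherry; then optional Gaussian blur and additive Gaussian noise.
Truth masks are recorded before noise, so every downstream value has an
exact expected answer.

- **Reporter geometry:** a half-plane cap through the EPI, placed at the
  pole opposite the TS attachment, with the offset found by bisection on
  the pixel-counted coverage (0.5 px offset resolution). Requested
  coverage is met within ±0.02 for EPI areas ≥ 2000 px; unreachable
  requests (degenerate, tiny regions) raise.
- **Time-lapse:** the reporter factor is exactly 1 up to and including
  the onset time, then rises linearly to its plateau over
  `ramp_duration` (default 6 h). Default frame times are 78–149 h at
  2 h steps. Each frame takes an independent noise realization derived
  deterministically from the base seed and frame index.
- **Capsules:** elongation fixtures are points within W/2 of a core
  segment/arc of length L − W, so the end-to-end centerline length is L,
  the analytic area is (L − W)·W + π(W/2)², and the widest inscribed
  circle has diameter W. An arc curvature κ (with κ·L < π) bends the
  core without changing its length.
- **Defaults as study conditions:** pixel size 1.3 µm/px and EPI
  semi-axes 70 × 55 px put embryoid diameters in the observed
  180–230 µm range; background 100, object foreground 200, reporter
  factor 2, noise SD 5 (5% of background). The rendered coordinate
  convention is row-major, 0-based, pixel centers at integer positions;
  a pixel belongs to a shape iff its center does.

What the generator deliberately does **not** emulate: 3D structure,
optics/PSF realism, shot (Poisson) noise, photobleaching, cell-scale
texture, or touching/multiple embryoids per well. Passing tests
demonstrate that the measurement definitions are implemented correctly
and are robust to additive noise at the stated levels — not that the
pipeline handles every artifact of real microscopy.

## Validation oracles

Every non-trivial computation is checked against an independent route:
min Feret against a 3600-direction projection sweep; inscribed-circle
radii against exhaustive pixel-pair distances; axial length against the
geodesic diameter of the morphological skeleton (skeletonize + Dijkstra
on the 8-connected skeleton graph — used only as a test oracle, never as
the measurement); coverage against brute-force pixel enumeration of the
half-plane cap. The blob fixtures for the skeleton comparison are chains
of 2–4 overlapping disks with radii 17–26 px; for near-round unions the
skeleton degenerates to rasterization spurs and a relative length
comparison would be meaningless.

## Problem sizes

Default validation sizes: 256² px frames; 50 embryoids for
coverage/positivity recovery; 20 seeded series of 13 frames (100–124 h)
for onset recovery; 50 random masks per geometric oracle; cohorts of 20
for the fraction-positive summary. These sizes give stable pass/fail
behavior (binomial noise on the recovery rates of a few percent) while
keeping the full suite under a minute.

## Known limitations

- Otsu thresholding assumes a bimodal histogram; with reporter signal
  below ~10% above background the reporter domain is statistically
  indistinguishable from background at 5% noise and coverage cannot be
  recovered by any thresholding method (these cases are negative by the
  positivity criterion, by design).
- The elongation index saturates at 0 below ~3:1 aspect ratios (see
  above) and the circle chain does not follow branches thinner than
  `stop_ratio × r₁`.
- One object per frame: touching embryoids are merged by the
  largest-component rule.
- Areas are 2D projections; no stereological correction is attempted.
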