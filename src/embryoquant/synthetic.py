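"""Synthetic embryoid image generator with exact ground truth.

Renders three-channel frames that emulate the measurement inputs of the
real pipeline: a bright elliptical epiblast-like (EPI) compartment and an
attached trophoblast (TS) disk in brightfield, the TS disk alone in GFP,
and a polarized T/Bra reporter domain in mCherry occupying a requested
fraction of the EPI at a requested intensity relative to background.
Optional Gaussian blur and additive Gaussian noise are applied after the
noise-free truth masks are recorded, so every downstream measurement can
be checked against exact expected values.

Conventions: row-major pixel grid, 0-based indices, pixel centers at
integer coordinates; a pixel belongs to a shape iff its center does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, MultiChannelImage

__all__ = [
    "GeneratorParams",
    "TimelapseParams",
    "GroundTruth",
    "generate_embryoid_image",
    "generate_capsule_mask",
    "generate_timelapse",
]

#: minimum clearance (px) between rendered object and the canvas border
FIT_MARGIN_PX = 5

#: guaranteed calibration of the rendered reporter coverage for EPI ≥ 2000 px
COVERAGE_TOL = 0.02


@dataclass
class GeneratorParams:
    """Parameters of one synthetic embryoid frame.

    Defaults emulate a typical epithelialized embryoid: at 1.3 µm/px an
    EPI ellipse with semi-axes 70 × 55 px spans ~180 × 140 µm, in the
    observed 180–230 µm diameter range, with a smaller attached TS disk.
    """

    canvas_size: tuple[int, int] = (256, 256)
    pixel_size: float = 1.3
    epi_semi_axes: tuple[float, float] = (70.0, 55.0)
    epi_orientation: float = 0.0
    ts_radius: float = 30.0
    ts_offset: float | None = None  # centre distance along major axis; default a + 0.6 r
    reporter_coverage: float = 0.4
    reporter_intensity_factor: float = 2.0
    background_level: float = 100.0
    foreground_level: float = 200.0
    noise_sd: float = 5.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        a, b = self.epi_semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("epi_semi_axes must be positive")
        if self.ts_radius < 0:
            raise ValueError("ts_radius must be >= 0")
        if not 0.0 <= self.reporter_coverage <= 1.0:
            raise ValueError("reporter_coverage must be in [0, 1]")
        if self.reporter_intensity_factor < 0:
            raise ValueError("reporter_intensity_factor must be >= 0")
        if self.background_level <= 0:
            raise ValueError("background_level must be > 0")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")
        if self.ts_offset is None:
            self.ts_offset = a + 0.6 * self.ts_radius if self.ts_radius > 0 else 0.0


@dataclass
class TimelapseParams:
    """A :class:`GeneratorParams` plus the temporal program of a series.

    The reporter intensity factor is 1 (indistinguishable from background
    in expectation) up to and including ``onset_time``, then rises
    linearly to ``base.reporter_intensity_factor`` over ``ramp_duration``
    hours.  Default frame times mirror a 78–149 h acquisition at 2 h
    intervals.  ``elongation_schedule`` optionally replaces the EPI
    ellipse with a curved capsule, interpolating (centerline length µm,
    width µm, curvature 1/µm) between the given time knots.
    """

    base: GeneratorParams = field(default_factory=GeneratorParams)
    frame_times: tuple[float, ...] = tuple(float(t) for t in range(78, 150, 2))
    onset_time: float = 110.0
    ramp_duration: float = 6.0
    elongation_schedule: dict[float, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.frame_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("frame_times must be non-empty and strictly increasing")
        if self.ramp_duration < 0:
            raise ValueError("ramp_duration must be >= 0")

    def factor_at(self, time_h: float) -> float:
        """Reporter intensity factor at a given time (piecewise linear)."""
        f = self.base.reporter_intensity_factor
        if time_h <= self.onset_time:
            return 1.0
        if self.ramp_duration == 0:
            return f
        frac = min(1.0, (time_h - self.onset_time) / self.ramp_duration)
        return 1.0 + (f - 1.0) * frac


@dataclass
class GroundTruth:
    """Exact values each measurement stage should recover.

    Masks are the noise-free supports; areas are pixel counts scaled by
    ``pixel_size**2`` (µm²).  EPI truth is the set difference
    brightfield \\ GFP, the reporter truth area the intersection of the
    reporter domain with the EPI, exactly as the measurement defines them.
    """

    bf_mask: np.ndarray
    ts_mask: np.ndarray
    reporter_mask: np.ndarray
    pixel_size: float
    area_total_um2: float = 0.0
    area_ts_um2: float = 0.0
    area_epi_um2: float = 0.0
    area_reporter_um2: float = 0.0
    area_anterior_epi_um2: float = 0.0
    coverage: float = 0.0
    intensity_factor: float = 1.0
    onset_h: float | None = None
    centerline_length_um: float | None = None
    width_um: float | None = None
    per_frame: list["GroundTruth"] | None = None

    @classmethod
    def from_masks(
        cls,
        bf_mask: np.ndarray,
        ts_mask: np.ndarray,
        reporter_mask: np.ndarray,
        pixel_size: float,
        intensity_factor: float = 1.0,
    ) -> "GroundTruth":
        epi = bf_mask & ~ts_mask
        reporter = reporter_mask & epi
        ps2 = pixel_size**2
        n_epi = int(epi.sum())
        return cls(
            bf_mask=bf_mask,
            ts_mask=ts_mask,
            reporter_mask=reporter_mask,
            pixel_size=pixel_size,
            area_total_um2=int(bf_mask.sum()) * ps2,
            area_ts_um2=int(ts_mask.sum()) * ps2,
            area_epi_um2=n_epi * ps2,
            area_reporter_um2=int(reporter.sum()) * ps2,
            area_anterior_epi_um2=int((epi & ~reporter).sum()) * ps2,
            coverage=(int(reporter.sum()) / n_epi) if n_epi else 0.0,
            intensity_factor=intensity_factor,
        )

    def scalars(self) -> dict:
        """JSON-serializable scalar truths (masks omitted)."""
        out = {
            "pixel_size": self.pixel_size,
            "area_total_um2": self.area_total_um2,
            "area_ts_um2": self.area_ts_um2,
            "area_epi_um2": self.area_epi_um2,
            "area_reporter_um2": self.area_reporter_um2,
            "area_anterior_epi_um2": self.area_anterior_epi_um2,
            "coverage": self.coverage,
            "intensity_factor": self.intensity_factor,
        }
        if self.onset_h is not None:
            out["onset_h"] = self.onset_h
        if self.centerline_length_um is not None:
            out["centerline_length_um"] = self.centerline_length_um
            out["width_um"] = self.width_um
        return out


def _pixel_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return rows.astype(float), cols.astype(float)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an ellipse; also return the major-axis coordinate grid."""
    rows, cols = _pixel_grid(shape)
    dr, dc = rows - center[0], cols - center[1]
    # orientation measured from the column (x) axis, counter-clockwise
    u = dc * np.cos(orientation) + dr * np.sin(orientation)
    v = -dc * np.sin(orientation) + dr * np.cos(orientation)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0, u


def _disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    rows, cols = _pixel_grid(shape)
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def _check_fit(object_mask: np.ndarray, margin: int = FIT_MARGIN_PX) -> None:
    interior = np.zeros_like(object_mask)
    interior[margin:-margin, margin:-margin] = True
    if np.any(object_mask & ~interior):
        raise ValueError(
            f"rendered object does not fit the canvas with a {margin} px margin"
        )


def solve_cap_offset(
    region: np.ndarray, axis_coord: np.ndarray, coverage: float
) -> np.ndarray:
    """Half-plane cap of ``region`` hitting a target area fraction.

    The cap is ``axis_coord >= c`` with the offset ``c`` found by bisection
    on the pixel-counted coverage (offset resolved to 0.5 px).  Raises if
    the best reachable coverage misses the request by more than the
    calibration tolerance (degenerate, very small regions).
    """
    n = int(region.sum())
    if n == 0:
        raise ValueError("cannot place a reporter cap in an empty region")
    if coverage <= 0.0:
        return np.zeros_like(region)
    if coverage >= 1.0:
        return region.copy()
    u = axis_coord[region]
    lo, hi = float(u.min()) - 1.0, float(u.max()) + 1.0  # full cap .. empty cap
    while hi - lo > 0.5:
        mid = 0.5 * (lo + hi)
        frac = np.count_nonzero(u >= mid) / n
        if frac > coverage:
            lo = mid
        else:
            hi = mid
    # pick the better of the two bracket ends
    best = min((lo, hi), key=lambda c: abs(np.count_nonzero(u >= c) / n - coverage))
    achieved = np.count_nonzero(u >= best) / n
    if abs(achieved - coverage) > COVERAGE_TOL:
        raise ValueError(
            f"requested coverage {coverage:.3f} unreachable on a region of "
            f"{n} px (best {achieved:.3f})"
        )
    return region & (axis_coord >= best)


def _render_channels(
    params: GeneratorParams,
    bf_mask: np.ndarray,
    ts_mask: np.ndarray,
    reporter_mask: np.ndarray,
    factor: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bg, fg = params.background_level, params.foreground_level
    bf = np.where(bf_mask, fg, bg).astype(float)
    gfp = np.where(ts_mask, fg, bg).astype(float)
    mch = bg * (1.0 + (factor - 1.0) * reporter_mask.astype(float))
    channels = []
    for img in (bf, gfp, mch):
        if params.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, params.blur_sigma)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, img.shape)
        channels.append(np.clip(img, 0.0, None))
    return tuple(channels)


def generate_embryoid_image(
    params: GeneratorParams,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic embryoid frame plus its exact ground truth.

    Channel contents (before blur/noise): brightfield = foreground on
    EPI ∪ TS; GFP = foreground on TS; mCherry = ``factor × background``
    on the reporter cap, background elsewhere.  The returned truth holds
    the noise-free masks and the derived areas/coverage.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.canvas_size
    a, b = params.epi_semi_axes

    # centre the EPI+TS union roughly on the canvas
    shift = params.ts_offset / 2.0 if params.ts_radius > 0 else 0.0
    center = (
        shape[0] / 2.0 - shift * np.sin(params.epi_orientation),
        shape[1] / 2.0 - shift * np.cos(params.epi_orientation),
    )
    epi_mask, u = _ellipse_mask(shape, center, (a, b), params.epi_orientation)
    if params.ts_radius > 0:
        ts_center = (
            center[0] + params.ts_offset * np.sin(params.epi_orientation),
            center[1] + params.ts_offset * np.cos(params.epi_orientation),
        )
        ts_mask = _disk_mask(shape, ts_center, params.ts_radius)
    else:
        ts_mask = np.zeros(shape, dtype=bool)
    bf_mask = epi_mask | ts_mask
    _check_fit(bf_mask)

    epi_only = epi_mask & ~ts_mask
    # polarize the reporter toward the pole opposite the TS attachment
    reporter_mask = solve_cap_offset(epi_only, -u, params.reporter_coverage)

    factor = params.reporter_intensity_factor
    bf, gfp, mch = _render_channels(params, bf_mask, ts_mask, reporter_mask, factor, rng)
    image = MultiChannelImage(
        bf, gfp, mch, pixel_size=params.pixel_size, identifier=f"synthetic-{params.seed}"
    )
    truth = GroundTruth.from_masks(
        bf_mask, ts_mask, reporter_mask, params.pixel_size, intensity_factor=factor
    )
    return image, truth


def _capsule_distance_um(
    shape: tuple[int, int],
    origin_um: tuple[float, float],
    pixel_size: float,
    core_length_um: float,
    curvature: float,
    orientation: float = 0.0,
) -> np.ndarray:
    """Distance (µm) of every pixel centre to the capsule core curve."""
    rows, cols = _pixel_grid(shape)
    x0 = cols * pixel_size - origin_um[1]
    y0 = rows * pixel_size - origin_um[0]
    # rotate pixel coordinates into the capsule frame (exact geometry)
    x = x0 * np.cos(orientation) + y0 * np.sin(orientation)
    y = -x0 * np.sin(orientation) + y0 * np.cos(orientation)
    if curvature == 0.0 or core_length_um == 0.0:
        half = core_length_um / 2.0
        dx = np.maximum(np.abs(x) - half, 0.0)
        return np.hypot(dx, y)
    radius = 1.0 / curvature
    span = core_length_um * curvature  # total arc angle
    # arc centre at (0, radius); arc points at angle t in [-span/2, span/2]
    vx, vy = x, y - radius
    ang = np.arctan2(vx, -vy)
    rad_dist = np.abs(np.hypot(vx, vy) - radius)
    t = span / 2.0
    end1 = (radius * np.sin(t), radius - radius * np.cos(t))
    end2 = (-end1[0], end1[1])
    d_ends = np.minimum(
        np.hypot(x - end1[0], y - end1[1]), np.hypot(x - end2[0], y - end2[1])
    )
    return np.where(np.abs(ang) <= t, rad_dist, d_ends)


def generate_capsule_mask(
    centerline_length: float,
    width: float,
    curvature: float = 0.0,
    pixel_size: float = 1.0,
    canvas_size: tuple[int, int] | None = None,
    orientation: float = 0.0,
) -> tuple[BinaryMask, GroundTruth]:
    """Rasterize a straight or arc-bent capsule of known geometry.

    The capsule is the set of points within ``width/2`` (µm) of a core
    curve of length ``centerline_length − width``, so the end-to-end
    centerline length (core plus the two hemispherical caps) equals the
    requested value and a maximal inscribed circle has diameter ``width``.
    ``curvature`` (1/µm) bends the core into a circular arc.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if centerline_length < width:
        raise ValueError("centerline_length must be >= width")
    if curvature < 0:
        raise ValueError("curvature must be >= 0")
    if curvature * centerline_length >= np.pi:
        raise ValueError("curvature * centerline_length must be < pi (self-overlap)")
    core = centerline_length - width

    # sample the core curve (µm), rotate it, and size the canvas to fit
    if curvature == 0.0 or core == 0.0:
        ts = np.linspace(-core / 2.0, core / 2.0, 201)
        pts = np.stack([ts, np.zeros_like(ts)], axis=1)
    else:
        radius = 1.0 / curvature
        half = core * curvature / 2.0
        ang = np.linspace(-half, half, 201)
        pts = np.stack([radius * np.sin(ang), radius * (1.0 - np.cos(ang))], axis=1)
    rot = np.array(
        [
            [np.cos(orientation), -np.sin(orientation)],
            [np.sin(orientation), np.cos(orientation)],
        ]
    )
    rpts = pts @ rot.T
    (x_min, y_min), (x_max, y_max) = rpts.min(axis=0), rpts.max(axis=0)
    pad = width / 2.0 + (FIT_MARGIN_PX + 1) * pixel_size
    if canvas_size is None:
        n_rows = int(np.ceil((y_max - y_min + 2 * pad) / pixel_size)) + 1
        n_cols = int(np.ceil((x_max - x_min + 2 * pad) / pixel_size)) + 1
        canvas_size = (n_rows, n_cols)
    origin = (pad - y_min, pad - x_min)  # world (row, col) of the curve frame, µm
    dist = _capsule_distance_um(
        canvas_size, origin, pixel_size, core, curvature, orientation
    )
    support = dist <= width / 2.0
    _check_fit(support)
    mask = BinaryMask(support, pixel_size)
    truth = GroundTruth.from_masks(
        support, np.zeros_like(support), np.zeros_like(support), pixel_size
    )
    truth.centerline_length_um = centerline_length
    truth.width_um = width
    return mask, truth


def _schedule_at(
    schedule: dict[float, tuple[float, float, float]], time_h: float
) -> tuple[float, float, float]:
    knots = sorted(schedule)
    vals = np.array([schedule[k] for k in knots], dtype=float)
    return tuple(
        float(np.interp(time_h, knots, vals[:, i])) for i in range(3)
    )


def generate_timelapse(
    params: TimelapseParams,
) -> tuple[list[MultiChannelImage], GroundTruth]:
    """Render one frame per time point with a known reporter onset.

    Each frame gets an independent noise realization (deterministically
    derived from the base seed and the frame index).  The returned series
    truth records the onset time and carries per-frame truths.
    """
    base = params.base
    frames: list[MultiChannelImage] = []
    per_frame: list[GroundTruth] = []
    for i, t in enumerate(params.frame_times):
        factor = params.factor_at(t)
        frame_seed = np.random.SeedSequence(entropy=[int(base.seed), i])
        rng = np.random.default_rng(frame_seed)
        if params.elongation_schedule:
            length, width, curv = _schedule_at(params.elongation_schedule, t)
            cap_mask, _ = generate_capsule_mask(
                length, width, curv, base.pixel_size, canvas_size=base.canvas_size
            )
            bf_mask = cap_mask.support
            ts_mask = np.zeros_like(bf_mask)
            # polarize the reporter cap along the capsule's column axis
            _, u = _pixel_grid(bf_mask.shape)
            reporter = solve_cap_offset(bf_mask, -u, base.reporter_coverage)
            bf, gfp, mch = _render_channels(base, bf_mask, ts_mask, reporter, factor, rng)
            image = MultiChannelImage(
                bf, gfp, mch, pixel_size=base.pixel_size,
                time_h=float(t), identifier=f"tl-{base.seed}-{i:03d}",
            )
            truth = GroundTruth.from_masks(
                bf_mask, ts_mask, reporter, base.pixel_size, intensity_factor=factor
            )
            truth.centerline_length_um = length
            truth.width_um = width
        else:
            frame_params = replace(
                base,
                reporter_intensity_factor=factor,
                seed=int(frame_seed.generate_state(1)[0] % (2**31)),
            )
            image, truth = generate_embryoid_image(frame_params)
            image.time_h = float(t)
            image.identifier = f"tl-{base.seed}-{i:03d}"
        frames.append(image)
        truth.onset_h = params.onset_time
        per_frame.append(truth)

    series_truth = GroundTruth(
        bf_mask=per_frame[-1].bf_mask,
        ts_mask=per_frame[-1].ts_mask,
        reporter_mask=per_frame[-1].reporter_mask,
        pixel_size=base.pixel_size,
        onset_h=params.onset_time,
        intensity_factor=base.reporter_intensity_factor,
        per_frame=per_frame,
    )
    return frames, series_truth
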