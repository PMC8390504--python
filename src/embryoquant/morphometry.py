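"""Per-embryoid scalar measurements.

Compartment areas follow set-difference semantics on the channel masks:
the EPI compartment is the brightfield object minus the GFP (TS) object,
the reporter compartment is the mCherry object intersected with the EPI,
and the anterior EPI is what remains of the EPI after removing the
reporter.  An embryoid is reporter-positive when the background-normalized
mean reporter intensity is at least 1.3 (signal ≥ 30% above background)
and the reporter compartment covers at least 1500 µm².  The coverage
index is the reporter area divided by the EPI area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, MultiChannelImage
from .segmentation import (
    FLAG_NO_OBJECT,
    BackgroundUndefinedError,
    SegmentationOptions,
    estimate_background,
    segment_channel,
)

__all__ = [
    "CompartmentAreas",
    "PositivityThresholds",
    "EmbryoidMeasurement",
    "compute_compartment_areas",
    "normalized_mean_intensity",
    "classify_reporter_positive",
    "coverage_index",
    "measure_frame",
]

FLAG_BACKGROUND_UNDEFINED = "background-undefined"
FLAG_RATIO_UNDEFINED = "ratio-undefined"
FLAG_COVERAGE_UNDEFINED = "coverage-undefined"
FLAG_REPORTER_OUTSIDE = "reporter-outside-object"


@dataclass
class CompartmentAreas:
    """All compartment areas of one embryoid, in µm²."""

    area_total: float
    area_ts: float
    area_epi: float
    area_reporter: float
    area_anterior_epi: float
    epi_support: np.ndarray | None = None
    reporter_support: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PositivityThresholds:
    """The reporter-positivity criterion: intensity ratio and area floor."""

    intensity_ratio_min: float = 1.3
    area_min: float = 1500.0

    def __post_init__(self) -> None:
        if self.intensity_ratio_min <= 1.0:
            raise ValueError("intensity_ratio_min must be > 1")
        if self.area_min <= 0:
            raise ValueError("area_min must be > 0")


@dataclass
class EmbryoidMeasurement:
    """Every per-embryoid scalar the pipeline reports for one frame."""

    identifier: str = ""
    time_h: float | None = None
    areas: CompartmentAreas | None = None
    normalized_mean_intensity: float = math.nan
    positive: bool = False
    coverage_index: float = math.nan
    background_level: float = math.nan
    flags: list[str] = field(default_factory=list)


def compute_compartment_areas(
    bf_mask: BinaryMask, gfp_mask: BinaryMask, mch_mask: BinaryMask
) -> CompartmentAreas:
    """Set-difference compartment arithmetic on the three channel masks.

    EPI = brightfield \\ GFP; reporter = mCherry ∩ EPI; anterior EPI =
    EPI \\ mCherry.  Mask (not scalar) arithmetic keeps every area
    non-negative even when the objects only partially overlap, and
    reduces to the plain area subtraction when they are nested.  Empty
    GFP or mCherry masks are valid (EPI-only aggregates, pre-onset
    frames); an empty brightfield mask yields all-zero areas with a
    ``"no-object"`` flag.
    """
    bf_mask.check_compatible(gfp_mask)
    bf_mask.check_compatible(mch_mask)
    ps2 = bf_mask.pixel_size**2
    if bf_mask.is_empty:
        z = np.zeros(bf_mask.shape, dtype=bool)
        return CompartmentAreas(0.0, 0.0, 0.0, 0.0, 0.0, z, z, flags=[FLAG_NO_OBJECT])
    epi = bf_mask.support & ~gfp_mask.support
    reporter = mch_mask.support & epi
    anterior = epi & ~mch_mask.support
    return CompartmentAreas(
        area_total=bf_mask.area_px * ps2,
        area_ts=gfp_mask.area_px * ps2,
        area_epi=int(epi.sum()) * ps2,
        area_reporter=int(reporter.sum()) * ps2,
        area_anterior_epi=int(anterior.sum()) * ps2,
        epi_support=epi,
        reporter_support=reporter,
    )


def normalized_mean_intensity(
    channel: np.ndarray, mask: BinaryMask, background: float
) -> float:
    """Mean intensity over the mask divided by the background level.

    Returns NaN (with the caller expected to flag it) for an empty mask;
    a non-positive background is a hard error.
    """
    if background <= 0:
        raise ValueError("background must be > 0")
    if mask.is_empty:
        return math.nan
    channel = np.asarray(channel, dtype=float)
    if channel.shape != mask.shape:
        raise ValueError("channel shape does not match mask")
    return float(channel[mask.support].mean()) / background


def classify_reporter_positive(
    ratio: float, reporter_area: float, thresholds: PositivityThresholds | None = None
) -> tuple[bool, dict]:
    """Apply the positivity criterion; both boundaries are inclusive.

    Positive iff ratio ≥ ``intensity_ratio_min`` AND reporter area ≥
    ``area_min``.  An undefined (NaN) ratio is negative with a flag in
    the criterion record.
    """
    thr = thresholds or PositivityThresholds()
    record = {
        "ratio": ratio,
        "reporter_area_um2": reporter_area,
        "intensity_ratio_min": thr.intensity_ratio_min,
        "area_min_um2": thr.area_min,
        "flags": [],
    }
    if math.isnan(ratio):
        record["flags"].append(FLAG_RATIO_UNDEFINED)
        return False, record
    positive = ratio >= thr.intensity_ratio_min and reporter_area >= thr.area_min
    return positive, record


def coverage_index(mch_mask: BinaryMask, epi_mask: BinaryMask) -> float:
    """Reporter-covered fraction of the EPI: |mCherry ∩ EPI| / |EPI|.

    Intersecting the numerator with the EPI bounds the index to [0, 1]
    even if the reporter object bleeds beyond the EPI compartment.
    Returns NaN for an empty EPI mask.
    """
    mch_mask.check_compatible(epi_mask)
    n_epi = epi_mask.area_px
    if n_epi == 0:
        return math.nan
    return int((mch_mask.support & epi_mask.support).sum()) / n_epi


def measure_frame(
    image: MultiChannelImage,
    bf_options: SegmentationOptions | None = None,
    gfp_options: SegmentationOptions | None = None,
    mch_options: SegmentationOptions | None = None,
    thresholds: PositivityThresholds | None = None,
    background_margin: int = 10,
    mch_background_offset: bool = False,
) -> EmbryoidMeasurement:
    """Run the full single-frame measurement.

    The three channels are segmented sequentially with their own options
    (Otsu by default).  The mCherry background is estimated outside the
    brightfield/GFP objects before the reporter is segmented; with
    ``mch_background_offset`` the reporter threshold is instead fixed at
    ``intensity_ratio_min × background`` (a background-offset threshold),
    so only pixels individually clearing the positivity ratio count as
    reporter signal.  Per-stage failures become flags on the returned
    measurement, never exceptions.
    """
    thr = thresholds or PositivityThresholds()
    flags: list[str] = []
    meas = EmbryoidMeasurement(identifier=image.identifier, time_h=image.time_h)

    try:
        bf_mask = segment_channel(image.brightfield, bf_options, image.pixel_size)
    except ValueError:
        bf_mask = BinaryMask(
            np.zeros(image.shape, dtype=bool), image.pixel_size, flags=[FLAG_NO_OBJECT]
        )
    try:
        gfp_mask = segment_channel(image.gfp, gfp_options, image.pixel_size)
    except ValueError:
        gfp_mask = BinaryMask(np.zeros(image.shape, dtype=bool), image.pixel_size)
    flags.extend(bf_mask.flags)

    try:
        background, _ = estimate_background(
            image.mcherry, [bf_mask, gfp_mask], exclusion_margin=background_margin
        )
    except BackgroundUndefinedError:
        flags.append(FLAG_BACKGROUND_UNDEFINED)
        meas.flags = flags
        return meas
    meas.background_level = background

    empty_mch = BinaryMask(np.zeros(image.shape, dtype=bool), image.pixel_size)
    if mch_background_offset:
        offset_thr = thr.intensity_ratio_min * background
        if image.mcherry.max() > offset_thr:
            mch_options = SegmentationOptions(
                method="fixed", threshold=offset_thr, min_object_area=0.0
            )
            mch_mask = segment_channel(image.mcherry, mch_options, image.pixel_size)
        else:  # nothing above the offset threshold: empty reporter object
            mch_mask = empty_mch
    else:
        # no area floor here: the 1500 µm² floor belongs to the positivity
        # criterion; the coverage index should see small domains too
        if mch_options is None:
            mch_options = SegmentationOptions(min_object_area=0.0)
        try:
            mch_mask = segment_channel(image.mcherry, mch_options, image.pixel_size)
        except ValueError:  # constant channel: no reporter signal
            mch_mask = empty_mch
    # colocalization guard: a real reporter domain lies inside the embryoid;
    # a signal-free channel thresholded on noise yields a sprawling component
    # mostly outside the brightfield object, which is rejected here
    if not mch_mask.is_empty and not bf_mask.is_empty:
        frac_in = (mch_mask.support & bf_mask.support).sum() / mch_mask.area_px
        if frac_in < 0.5:
            mch_mask = empty_mch
            flags.append(FLAG_REPORTER_OUTSIDE)

    areas = compute_compartment_areas(bf_mask, gfp_mask, mch_mask)
    flags.extend(f for f in areas.flags if f not in flags)
    meas.areas = areas

    epi_mask = BinaryMask(areas.epi_support, image.pixel_size)
    cov = coverage_index(mch_mask, epi_mask)
    if math.isnan(cov):
        flags.append(FLAG_COVERAGE_UNDEFINED)
    meas.coverage_index = cov

    reporter_mask = BinaryMask(areas.reporter_support, image.pixel_size)
    ratio = normalized_mean_intensity(image.mcherry, reporter_mask, background)
    meas.normalized_mean_intensity = ratio
    positive, record = classify_reporter_positive(ratio, areas.area_reporter, thr)
    flags.extend(f for f in record["flags"] if f not in flags)
    meas.positive = positive
    meas.flags = flags
    return meas
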