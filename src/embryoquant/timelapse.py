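"""Time-lapse measurement and onset-of-expression detection.

Each frame of a series is measured independently (segmentation +
morphometry, with the background re-estimated per frame to tolerate
illumination drift), and the onset of reporter expression is the
earliest frame at which the positivity criterion holds — optionally for
several consecutive frames (``persistence``) to debounce noisy calls.
Cohort summaries report the fraction of embryoids positive at a given
time point.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MultiChannelImage
from .morphometry import (
    EmbryoidMeasurement,
    PositivityThresholds,
    SegmentationOptions,
    measure_frame,
)

__all__ = [
    "TimelapseSeries",
    "OnsetResult",
    "measure_series",
    "detect_onset",
    "fraction_positive",
]

FLAG_FRAME_ERROR = "frame-error"


@dataclass
class TimelapseSeries:
    """Ordered (time_h, frame) pairs for one embryoid."""

    frames: list[tuple[float, MultiChannelImage]]
    identifier: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty time-lapse series")
        times = [t for t, _ in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        sizes = {img.pixel_size for _, img in self.frames}
        if len(sizes) > 1:
            raise ValueError("all frames must share one pixel size")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.frames]


@dataclass
class OnsetResult:
    """Detected onset plus the per-frame measurements behind it."""

    identifier: str
    onset_h: float | None
    per_frame: list[tuple[float, EmbryoidMeasurement]]
    persistence_used: int = 1


def measure_series(
    series: TimelapseSeries,
    bf_options: SegmentationOptions | None = None,
    gfp_options: SegmentationOptions | None = None,
    mch_options: SegmentationOptions | None = None,
    thresholds: PositivityThresholds | None = None,
    mch_background_offset: bool = False,
) -> list[tuple[float, EmbryoidMeasurement]]:
    """Measure every frame independently; frame failures become flags."""
    results: list[tuple[float, EmbryoidMeasurement]] = []
    for time_h, image in series.frames:
        try:
            meas = measure_frame(
                image,
                bf_options=bf_options,
                gfp_options=gfp_options,
                mch_options=mch_options,
                thresholds=thresholds,
                mch_background_offset=mch_background_offset,
            )
        except Exception as exc:  # frame-level failure never aborts the series
            meas = EmbryoidMeasurement(
                identifier=image.identifier,
                time_h=time_h,
                flags=[FLAG_FRAME_ERROR, f"{type(exc).__name__}: {exc}"],
            )
        meas.time_h = time_h
        results.append((time_h, meas))
    return results


def detect_onset(
    calls: list[tuple[float, bool]], persistence: int = 1
) -> float | None:
    """Earliest time at which ``persistence`` consecutive calls are positive.

    Returns the frame time (never interpolated between frames), or None
    when no sufficiently persistent positive run exists.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    times = [t for t, _ in calls]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("call times must be strictly increasing")
    flags = [bool(p) for _, p in calls]
    for i in range(len(flags) - persistence + 1):
        if all(flags[i : i + persistence]):
            return times[i]
    return None


def detect_onset_from_measurements(
    measurements: list[tuple[float, EmbryoidMeasurement]],
    persistence: int = 1,
    identifier: str = "",
) -> OnsetResult:
    calls = [(t, m.positive) for t, m in measurements]
    onset = detect_onset(calls, persistence=persistence)
    return OnsetResult(
        identifier=identifier,
        onset_h=onset,
        per_frame=measurements,
        persistence_used=persistence,
    )


def fraction_positive(
    cohort: list[OnsetResult], at_time_h: float
) -> tuple[float, int, int, int]:
    """Fraction of embryoids positive at (or latest before) a time point.

    For each member the call at the latest frame with time ≤ ``at_time_h``
    is used; members with no usable frame at or before that time are
    excluded and counted separately.  Returns
    ``(fraction, n_positive, n_total, n_excluded)``.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n_pos = n_tot = n_excl = 0
    for member in cohort:
        usable = [
            (t, m) for t, m in member.per_frame
            if t <= at_time_h and FLAG_FRAME_ERROR not in m.flags
        ]
        if not usable:
            n_excl += 1
            continue
        _, latest = max(usable, key=lambda tm: tm[0])
        n_tot += 1
        n_pos += int(latest.positive)
    if n_tot == 0:
        raise ValueError(f"no cohort member has a usable frame at or before {at_time_h} h")
    return n_pos / n_tot, n_pos, n_tot, n_excl
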