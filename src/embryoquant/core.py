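"""Core containers shared by every stage of the pipeline.

A frame is a set of co-registered 2D intensity grids (brightfield, GFP,
mCherry) with a physical pixel size in µm/px; segmentation produces
:class:`BinaryMask` objects on the same grid.  All areas downstream are
pixel counts scaled by ``pixel_size**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultiChannelImage", "BinaryMask", "CHANNEL_NAMES"]

#: canonical channel order used throughout (TIFF page order, config keys)
CHANNEL_NAMES = ("brightfield", "gfp", "mcherry")


@dataclass
class MultiChannelImage:
    """One acquisition frame: three co-registered channels plus calibration.

    Parameters
    ----------
    brightfield, gfp, mcherry
        2D non-negative float arrays of identical shape.  Brightfield
        delineates the whole embryoid, GFP the trophoblast (TS)
        compartment, mCherry the T/Bra reporter.
    pixel_size
        Physical pixel size in µm/px (> 0).
    time_h
        Acquisition time in hours, if part of a time-lapse.
    identifier
        Free-form frame label carried through to result tables.
    """

    brightfield: np.ndarray
    gfp: np.ndarray
    mcherry: np.ndarray
    pixel_size: float
    time_h: float | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        shape = self.brightfield.shape
        if self.gfp.shape != shape or self.mcherry.shape != shape:
            raise ValueError(
                f"channel shapes differ: brightfield {shape}, "
                f"gfp {self.gfp.shape}, mcherry {self.mcherry.shape}"
            )
        if self.brightfield.ndim != 2:
            raise ValueError("channels must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name in CHANNEL_NAMES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite intensities in {name} channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")
        return getattr(self, name)


@dataclass
class BinaryMask:
    """Support of one segmented object on the pixel grid."""

    support: np.ndarray
    pixel_size: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)
        if self.support.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.support.shape

    @property
    def area_px(self) -> int:
        return int(self.support.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    @property
    def is_empty(self) -> bool:
        return not self.support.any()

    def check_compatible(self, other: "BinaryMask") -> None:
        """Raise if two masks cannot be combined pixelwise."""
        if self.shape != other.shape:
            raise ValueError(f"mask shape mismatch: {self.shape} vs {other.shape}")
        if not np.isclose(self.pixel_size, other.pixel_size):
            raise ValueError(
                f"pixel size mismatch: {self.pixel_size} vs {other.pixel_size}"
            )
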