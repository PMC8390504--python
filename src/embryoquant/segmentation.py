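"""Per-channel segmentation and basic mask geometry.

Each channel of a frame is reduced to a single-object binary mask:
threshold (Otsu by default, or a fixed value), keep the largest
8-connected component, fill holes, and discard the result if it is
smaller than a physical area floor.  A background level is estimated
from the pixels outside all segmented objects, and the minimum Feret
(caliper) diameter of a mask is computed by rotating calipers on the
convex hull of pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu

from .core import BinaryMask

__all__ = [
    "SegmentationOptions",
    "segment_channel",
    "estimate_background",
    "min_feret_diameter",
    "BackgroundUndefinedError",
]

FLAG_NO_OBJECT = "no-object"


class BackgroundUndefinedError(ValueError):
    """Too few pixels outside the objects to estimate a background level."""


@dataclass
class SegmentationOptions:
    """How one channel is binarized.

    ``method`` is ``"auto"`` (Otsu) or ``"fixed"`` (use ``threshold``);
    ``polarity`` selects whether the object is brighter or darker than
    background; components below ``min_object_area`` µm² (default the
    1500 µm² floor used for reporter positivity) are rejected.
    """

    method: str = "auto"
    threshold: float | None = None
    polarity: str = "bright-object"
    min_object_area: float = 1500.0
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("auto", "fixed"):
            raise ValueError("method must be 'auto' or 'fixed'")
        if self.method == "fixed" and self.threshold is None:
            raise ValueError("fixed method requires a threshold value")
        if self.polarity not in ("bright-object", "dark-object"):
            raise ValueError("polarity must be 'bright-object' or 'dark-object'")


_STRUCT8 = np.ones((3, 3), dtype=bool)


def segment_channel(
    channel: np.ndarray,
    options: SegmentationOptions | None = None,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Binarize one channel into at most one object.

    Returns the largest 8-connected above-threshold component with holes
    filled.  If that component is smaller than ``min_object_area`` the
    returned mask is empty and flagged ``"no-object"`` — a valid result,
    not an error.  A constant image under the auto method raises, since
    Otsu's threshold is undefined there.
    """
    options = options or SegmentationOptions()
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite intensities")

    if options.method == "auto":
        if np.ptp(channel) == 0:
            raise ValueError("threshold undefined: constant image under auto method")
        thr = threshold_otsu(channel)
    else:
        thr = float(options.threshold)
        lo, hi = channel.min(), channel.max()
        if not lo <= thr <= hi:
            raise ValueError(
                f"fixed threshold {thr} outside channel intensity range [{lo}, {hi}]"
            )
    binary = channel > thr if options.polarity == "bright-object" else channel < thr

    labels, n = ndimage.label(binary, structure=_STRUCT8)
    if n == 0:
        return BinaryMask(np.zeros_like(binary), pixel_size, flags=[FLAG_NO_OBJECT])
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    support = labels == (int(np.argmax(sizes)) + 1)
    if options.fill_holes:
        support = ndimage.binary_fill_holes(support)
    if support.sum() * pixel_size**2 < options.min_object_area:
        return BinaryMask(np.zeros_like(support), pixel_size, flags=[FLAG_NO_OBJECT])
    return BinaryMask(support, pixel_size)


def estimate_background(
    channel: np.ndarray,
    object_masks: list[BinaryMask] | None = None,
    exclusion_margin: int = 10,
    min_pixels: int = 500,
) -> tuple[float, int]:
    """Mean intensity outside all objects, dilated by a safety margin.

    Returns ``(level, n_pixels_used)``.  Raises
    :class:`BackgroundUndefinedError` when fewer than ``min_pixels``
    pixels remain outside the dilated object union.
    """
    channel = np.asarray(channel, dtype=float)
    exclude = np.zeros(channel.shape, dtype=bool)
    for mask in object_masks or []:
        if mask.shape != channel.shape:
            raise ValueError("object mask shape does not match channel")
        exclude |= mask.support
    if exclusion_margin > 0 and exclude.any():
        exclude = ndimage.binary_dilation(
            exclude, structure=_STRUCT8, iterations=exclusion_margin
        )
    outside = ~exclude
    n = int(outside.sum())
    if n < min_pixels:
        raise BackgroundUndefinedError(
            f"background undefined: only {n} pixels outside objects (< {min_pixels})"
        )
    return float(channel[outside].mean()), n


def _hull_points(mask: BinaryMask) -> np.ndarray:
    pts = np.argwhere(mask.support).astype(float)
    if len(pts) == 0:
        raise ValueError("min_feret_diameter: empty mask")
    return pts


def min_feret_diameter(mask: BinaryMask) -> float:
    """Minimum caliper (projection) width of the object, in µm.

    Computed over the convex hull of true-pixel centers by the rotating
    calipers principle: the minimum width is attained with one hull edge
    flush against a caliper jaw, so it suffices to take, for each hull
    edge, the farthest hull vertex from the edge's line, and minimize
    over edges.  One pixel is added before scaling because pixel centers
    under-span the physical pixel extent by half a pixel on each side.
    """
    pts = _hull_points(mask)
    try:
        hull = ConvexHull(pts)
        vertices = pts[hull.vertices]
    except QhullError:
        # collinear or single-pixel mask: width is zero across the line
        d = pts - pts.mean(axis=0)
        if len(pts) > 1 and np.linalg.norm(d, axis=1).max() > 0:
            # project onto the normal of the dominant direction
            _, _, vt = np.linalg.svd(d, full_matrices=False)
            widths = d @ vt[-1]
            return (widths.max() - widths.min() + 1.0) * mask.pixel_size
        return 1.0 * mask.pixel_size

    edges = np.roll(vertices, -1, axis=0) - vertices
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    normals = np.stack([-edges[keep][:, 1], edges[keep][:, 0]], axis=1)
    normals /= lengths[keep, None]
    # distance of every vertex to every edge line; max over vertices, min over edges
    proj = vertices @ normals.T  # (n_vertices, n_edges)
    base = np.einsum("ij,ij->i", vertices[keep], normals)
    width = np.min(np.max(np.abs(proj - base[None, :]), axis=0))
    return (width + 1.0) * mask.pixel_size
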