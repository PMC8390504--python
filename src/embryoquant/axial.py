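"""Axial shape scoring by chains of maximal inscribed circles.

A round object admits one large inscribed circle; a tube admits a chain
of similar-radius circles strung along its midline.  The axial length is
the length of the path connecting the chain's centers, and the
elongation index is that length divided by the diameter of the largest
inscribed circle — 0 for a disk, (L − W)/W for a straight capsule of
end-to-end length L and width W, growing as the object elongates.

Circles are found on the Euclidean distance transform (EDT) of the mask:
the maximal inscribed circle sits at the EDT arg-max with the EDT value
as its radius.  Subsequent circles are placed greedily at the EDT
arg-max over the not-yet-covered part of the object, with radii always
measured against the original boundary so the chain tracks the true
local half-width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask

__all__ = [
    "InscribedCircle",
    "CircleChain",
    "ChainParams",
    "ElongationResult",
    "max_inscribed_circle",
    "subtract_ts_mask",
    "fit_circle_chain",
    "elongation_index",
    "save_chain_overlay",
]

FLAG_NO_EPI = "no-epi-object"

#: EDT near-tie tolerance (px): centers within this of the relevant EDT
#: maximum are treated as interchangeable candidates
TIE_TOL = 1.0


@dataclass(frozen=True)
class InscribedCircle:
    """One inscribed circle: center in (row, col) pixel coordinates, radius in px."""

    center: tuple[float, float]
    radius: float


@dataclass
class ChainParams:
    """Stopping rules of the greedy chain.

    The chain stops when the next circle's radius falls below
    ``stop_ratio`` times the first (largest) radius, when the placed
    disks cover at least ``coverage_stop`` of the object, or at
    ``max_circles``.
    """

    stop_ratio: float = 0.5
    coverage_stop: float = 0.95
    max_circles: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.stop_ratio < 1:
            raise ValueError("stop_ratio must be in (0, 1)")
        if not 0 < self.coverage_stop <= 1:
            raise ValueError("coverage_stop must be in (0, 1]")
        if self.max_circles < 1:
            raise ValueError("max_circles must be >= 1")


@dataclass
class CircleChain:
    """Ordered inscribed circles whose center path defines the axial length."""

    circles: list[InscribedCircle]
    pixel_size: float

    @property
    def max_diameter_um(self) -> float:
        if not self.circles:
            raise ValueError("empty circle chain")
        return 2.0 * max(c.radius for c in self.circles) * self.pixel_size

    @property
    def axial_length_um(self) -> float:
        if not self.circles:
            raise ValueError("empty circle chain")
        centers = np.array([c.center for c in self.circles])
        if len(centers) == 1:
            return 0.0
        steps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        return float(steps.sum()) * self.pixel_size


@dataclass
class ElongationResult:
    axial_length_um: float
    max_inscribed_diameter_um: float
    elongation_index: float
    n_circles: int


def _edt(support: np.ndarray) -> np.ndarray:
    """EDT with the image border treated as background."""
    padded = np.pad(support, 1)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


def _argmax_first(values: np.ndarray, where: np.ndarray) -> tuple[int, int]:
    """Arg-max of ``values`` over ``where``; ties broken by row, then column."""
    masked = np.where(where, values, -np.inf)
    idx = int(np.argmax(masked))  # C order: first max = smallest row, then col
    return np.unravel_index(idx, values.shape)


def max_inscribed_circle(mask: BinaryMask) -> InscribedCircle:
    """Largest circle fitting inside the object.

    Radius is the maximum of the Euclidean distance transform (distance
    of interior pixel centers to the nearest exterior pixel center);
    the center is the arg-max, ties broken by smallest row then column.
    """
    if mask.is_empty:
        raise ValueError("max_inscribed_circle: empty mask")
    edt = _edt(mask.support)
    r, c = _argmax_first(edt, mask.support)
    return InscribedCircle(center=(float(r), float(c)), radius=float(edt[r, c]))


def subtract_ts_mask(bf_mask: BinaryMask, gfp_mask: BinaryMask) -> BinaryMask:
    """Remove the TS compartment before elongation scoring: BF \\ GFP.

    The subtraction may fragment the object, so only the largest
    8-connected remnant is kept; an empty result is returned flagged,
    not raised.
    """
    bf_mask.check_compatible(gfp_mask)
    remainder = bf_mask.support & ~gfp_mask.support
    labels, n = ndimage.label(remainder, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return BinaryMask(remainder, bf_mask.pixel_size, flags=[FLAG_NO_EPI])
    sizes = ndimage.sum_labels(remainder, labels, index=np.arange(1, n + 1))
    return BinaryMask(labels == (int(np.argmax(sizes)) + 1), bf_mask.pixel_size)


def fit_circle_chain(mask: BinaryMask, params: ChainParams | None = None) -> CircleChain:
    """Greedy chain of inscribed circles along the object.

    Circle 1 is the maximal inscribed circle.  Each subsequent circle is
    centered at the EDT arg-max over the not-yet-covered region (object
    minus the union of already-placed disks), its radius read from the
    EDT of the *original* mask.  Iteration stops per
    :class:`ChainParams`.  Centers are then ordered into a path by
    nearest-neighbor chaining starting from the most eccentric center
    (greatest distance to any other center).
    """
    params = params or ChainParams()
    if mask.is_empty:
        raise ValueError("fit_circle_chain: empty mask")
    support = mask.support
    edt = _edt(support)
    rows, cols = np.mgrid[0 : support.shape[0], 0 : support.shape[1]]

    covered = np.zeros_like(support)
    area = support.sum()
    circles: list[InscribedCircle] = []
    r1 = None
    while len(circles) < params.max_circles:
        uncovered = support & ~covered
        if not uncovered.any():
            break
        if not circles:
            # circle 1: a maximal inscribed circle.  On elongated shapes
            # the EDT maximum sits on a near-tied plateau along the
            # midline; seed at the plateau point nearest the plateau
            # centroid so the chain grows symmetrically toward both
            # ends regardless of rasterization order (rotation-stable).
            plateau = np.argwhere(edt >= edt.max() - TIE_TOL).astype(float)
            centroid = plateau.mean(axis=0)
            r, c = plateau[
                int(np.argmin(np.linalg.norm(plateau - centroid, axis=1)))
            ].astype(int)
            r1 = float(edt[r, c])
        else:
            # Subsequent centers maximize the EDT of the *uncovered*
            # region: the point around which the largest fresh disk
            # fits.  Thin leftover slivers along the already-covered
            # boundary have a tiny uncovered-EDT, so they never attract
            # circles, which keeps the chain on the object's midline.
            # Among near-maximal candidates (within 1 px of the best
            # fresh radius) the one farthest from the placed centers is
            # taken, so chains extend end-to-end.
            edt_u = _edt(uncovered)
            if edt_u.max() < params.stop_ratio * r1:
                break
            centers = np.array([circ.center for circ in circles])
            cand_rc = np.argwhere(edt_u >= edt_u.max() - TIE_TOL).astype(float)
            d = np.linalg.norm(
                cand_rc[:, None, :] - centers[None, :, :], axis=2
            ).min(axis=1)
            r, c = cand_rc[int(np.argmax(d))].astype(int)
        # radii are always measured against the original mask boundary
        radius = float(edt[r, c])
        if radius < params.stop_ratio * r1:
            break
        circles.append(InscribedCircle(center=(float(r), float(c)), radius=radius))
        covered |= (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
        if (covered & support).sum() / area >= params.coverage_stop:
            break

    return CircleChain(_order_path(circles), mask.pixel_size)


def _order_path(circles: list[InscribedCircle]) -> list[InscribedCircle]:
    if len(circles) <= 2:
        return circles
    centers = np.array([c.center for c in circles])
    dists = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    start = int(np.argmax(dists.max(axis=1)))
    order = [start]
    remaining = set(range(len(circles))) - {start}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda i: dists[last, i])
        order.append(nxt)
        remaining.remove(nxt)
    return [circles[i] for i in order]


def elongation_index(chain: CircleChain) -> ElongationResult:
    """Axial length over maximal-inscribed-circle diameter (dimensionless)."""
    if not chain.circles:
        raise ValueError("elongation_index: empty chain")
    d = chain.max_diameter_um
    if d <= 0:
        raise ValueError("elongation_index: zero max inscribed diameter")
    length = chain.axial_length_um
    return ElongationResult(
        axial_length_um=length,
        max_inscribed_diameter_um=d,
        elongation_index=length / d,
        n_circles=len(chain.circles),
    )


def save_chain_overlay(mask: BinaryMask, chain: CircleChain, path) -> None:
    """QC overlay: mask outline, fitted circles, and the center path (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(mask.support, cmap="gray", interpolation="nearest")
    centers = np.array([c.center for c in chain.circles])
    for circ in chain.circles:
        ax.add_patch(
            plt.Circle(
                (circ.center[1], circ.center[0]),
                circ.radius,
                fill=False,
                color="tab:red",
                linewidth=1,
            )
        )
    if len(centers) > 1:
        ax.plot(centers[:, 1], centers[:, 0], "o-", color="tab:cyan", markersize=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
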