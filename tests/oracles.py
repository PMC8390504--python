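"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a method unrelated to the library's
implementation: directional sweeps instead of rotating calipers,
exhaustive pixel-pair distances instead of the distance transform, and
skeleton geodesics instead of inscribed-circle chains.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize


def brute_force_min_feret(support: np.ndarray, n_directions: int = 3600) -> float:
    """Minimum projection width over a dense directional sweep, +1 px."""
    pts = np.argwhere(support).astype(float)
    best = np.inf
    for theta in np.linspace(0.0, np.pi, n_directions, endpoint=False):
        d = pts @ np.array([np.cos(theta), np.sin(theta)])
        best = min(best, d.max() - d.min())
    return best + 1.0


def brute_force_inscribed_radius(support: np.ndarray) -> float:
    """Max over interior pixels of the min distance to any exterior pixel."""
    padded = np.pad(support, 1)
    exterior = np.argwhere(~padded)
    interior = np.argwhere(padded)
    dist, _ = cKDTree(exterior).query(interior)
    return float(dist.max())


def skeleton_geodesic_diameter(support: np.ndarray) -> float:
    """Geodesic diameter of the morphological skeleton (8-connected graph)."""
    skel = skeletonize(support)
    pts = np.argwhere(skel)
    if len(pts) < 2:
        return 0.0
    index = {tuple(p): i for i, p in enumerate(map(tuple, pts))}
    graph = nx.Graph()
    graph.add_nodes_from(range(len(pts)))
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) != (0, 0) and (r + dr, c + dc) in index:
                    graph.add_edge(i, index[(r + dr, c + dc)], weight=float(np.hypot(dr, dc)))
    best = 0.0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        start = next(iter(comp))
        far = max(
            (d := nx.single_source_dijkstra_path_length(sub, start)), key=d.get
        )
        lengths = nx.single_source_dijkstra_path_length(sub, far)
        best = max(best, max(lengths.values()))
    return best


def analytic_capsule_area(length: float, width: float) -> float:
    """Area of a straight capsule of end-to-end length L and width W."""
    return (length - width) * width + np.pi * (width / 2.0) ** 2


def random_disk_union(
    rng: np.random.Generator,
    n_disks: tuple[int, int] = (1, 4),
    radius_range: tuple[float, float] = (4.0, 12.0),
    size: int = 64,
) -> np.ndarray:
    """Union of a few random disks on a small canvas (may be disconnected)."""
    support = np.zeros((size, size), dtype=bool)
    rr, cc = np.mgrid[0:size, 0:size]
    for _ in range(int(rng.integers(n_disks[0], n_disks[1] + 1))):
        r0, c0 = rng.integers(size // 5, size - size // 5, 2)
        radius = rng.uniform(*radius_range)
        support |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    if not support.any():
        support[size // 2, size // 2] = True
    return support


def random_blob_chain(rng: np.random.Generator) -> np.ndarray:
    """Blobby elongated mask: 2-4 overlapping disks arranged in a chain.

    Radii 17-26 px with centers stepped by 0.8x the radius sum and small
    heading changes, so the union is a connected, tube-ish blob whose
    skeleton geodesic diameter is a meaningful length reference.
    """
    n = int(rng.integers(2, 5))
    radii = rng.uniform(17.0, 26.0, n)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    centers = [np.zeros(2)]
    for k in range(1, n):
        theta += rng.uniform(-0.6, 0.6)
        step = 0.8 * (radii[k - 1] + radii[k])
        centers.append(centers[-1] + step * np.array([np.sin(theta), np.cos(theta)]))
    centers = np.array(centers)
    centers -= centers.min(axis=0) - radii.max() - 6.0
    size = (centers.max(axis=0) + radii.max() + 6.0).astype(int) + 1
    rr, cc = np.mgrid[0 : size[0], 0 : size[1]]
    support = np.zeros(tuple(size), dtype=bool)
    for (y, x), radius in zip(centers, radii):
        support |= (rr - y) ** 2 + (cc - x) ** 2 <= radius**2
    return support
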