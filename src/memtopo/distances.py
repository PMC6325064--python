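"""The three distance notions used to quantify spread on a surface.

For two nodes ``a = (x1, y1, z1)`` and ``b = (x2, y2, z2)``:

* 2D Euclidean: ``sqrt(dx^2 + dy^2)`` — the straight line in the imaging
  plane, ignoring height (what 2D single-particle tracking measures);
* 3D Euclidean: ``sqrt(dx^2 + dy^2 + dz^2)`` — the straight line through the
  volume, which may leave the surface;
* SWSD, the shortest-within-surface distance: the geodesic along
  face-adjacent surface nodes, with every hop counting one node unit
  (orthogonal propagation, i.e. the city-block metric on the surface: a
  (3, 4) planar offset on a flat sheet measures 7, not 5).

Both straight-line distances allow physically impossible paths on non-flat
surfaces; the SWSD never leaves the surface.  Because the SWSD is city-block
even on a flat sheet, it is systematically longer than the Euclidean measures
there; analyses factor this out by normalising against a flat baseline
(see :mod:`memtopo.analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .surfaces import SurfaceGraph

__all__ = [
    "METRICS",
    "normalize_metric",
    "euclidean_2d",
    "euclidean_3d",
    "geodesic_transform",
    "compute_distance_maps",
    "DistanceMaps",
]


METRICS = ("2d", "3d", "swsd")


def normalize_metric(name: str) -> str:
    """Canonical metric key: accepts e.g. '2d', 'd3', 'msd_swsd', 'drel_2d'."""
    key = str(name).lower()
    for prefix in ("msd_", "drel_", "d_"):
        if key.startswith(prefix):
            key = key[len(prefix):]
    if key in ("d2", "d3"):
        key = key[1] + "d"
    if key == "dswsd":
        key = "swsd"
    if key not in METRICS:
        raise InvalidSpecError(f"unknown metric {name!r}; expected one of {METRICS}")
    return key


def euclidean_2d(a, b) -> float | np.ndarray:
    """Planar straight-line distance; the z coordinate is ignored."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return np.hypot(b[..., 0] - a[..., 0], b[..., 1] - a[..., 1])


def euclidean_3d(a, b) -> float | np.ndarray:
    """Straight-line distance through the volume."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return np.sqrt(((b - a) ** 2).sum(axis=-1))


def geodesic_transform(surface: SurfaceGraph, start) -> np.ndarray:
    """Shortest-within-surface distance from ``start`` to every node.

    Implemented as a level-synchronous wavefront: the front at distance ``d``
    claims all unvisited face-neighbours at distance ``d + 1``.  All hops
    weigh one node unit, so the result is an exact integer hop count (stored
    as float); nodes not reachable from ``start`` are ``inf``.  The result is
    independent of the order in which the front visits nodes because levels
    are expanded synchronously.
    """
    start_id = surface.node_id(start)
    A = surface.adjacency
    indptr, indices = A.indptr, A.indices
    dist = np.full(surface.n_nodes, np.inf)
    dist[start_id] = 0.0
    frontier = np.array([start_id], dtype=np.int64)
    d = 0.0
    while frontier.size:
        starts = indptr[frontier]
        cnt = indptr[frontier + 1] - starts
        total = int(cnt.sum())
        if total == 0:
            break
        first = np.cumsum(cnt) - cnt
        gather = np.repeat(starts - first, cnt) + np.arange(total)
        nbrs = indices[gather]
        fresh = nbrs[np.isinf(dist[nbrs])]
        if fresh.size == 0:
            break
        frontier = np.unique(fresh)
        d += 1.0
        dist[frontier] = d
    return dist


@dataclass
class DistanceMaps:
    """Per-node distances from a single start node, one array per metric.

    ``d2 <= d3 <= dswsd`` holds node-wise: the planar line is never longer
    than the 3D line, and any surface path is at least as long as the 3D
    straight line between its endpoints (each hop advances at most one unit
    in one coordinate).
    """

    surface: SurfaceGraph
    start: int
    d2: np.ndarray
    d3: np.ndarray
    dswsd: np.ndarray
    metrics: tuple[str, ...] = field(default=("2d", "3d", "swsd"), repr=False)

    def metric(self, name: str) -> np.ndarray:
        key = normalize_metric(name)
        return {"2d": self.d2, "3d": self.d3, "swsd": self.dswsd}[key]

    @property
    def start_node(self) -> tuple[int, int, int]:
        return tuple(int(c) for c in self.surface.nodes[self.start])

    def to_frame(self) -> pd.DataFrame:
        nodes = self.surface.nodes
        return pd.DataFrame(
            {
                "x": nodes[:, 0],
                "y": nodes[:, 1],
                "z": nodes[:, 2],
                "d2": self.d2,
                "d3": self.d3,
                "dswsd": self.dswsd,
            }
        )


def compute_distance_maps(surface: SurfaceGraph, start) -> DistanceMaps:
    """All three distance maps from ``start`` (a node triple or node id)."""
    start_id = surface.node_id(start)
    origin = surface.nodes[start_id].astype(np.float64)
    nodes = surface.nodes.astype(np.float64)
    d2 = np.hypot(nodes[:, 0] - origin[0], nodes[:, 1] - origin[1])
    d3 = np.sqrt(((nodes - origin) ** 2).sum(axis=1))
    dswsd = geodesic_transform(surface, start_id)
    return DistanceMaps(surface=surface, start=start_id, d2=d2, d3=d3, dswsd=dswsd)
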