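"""Voxelized surface graphs.

A surface is a set of cubic nodes at integer coordinates ``(x, y, z)`` inside a
3D volume, connected by face adjacency (6-connectivity).  Node spacing is one
distance unit everywhere; ``x`` and ``y`` span the imaging plane and ``z`` is
height.  The graph of face-adjacent surface nodes is the single source of
truth for "within the surface": diffusion, geodesic distances and analysis all
operate on it.

Two classes of surface matter for diffusion analysis:

* **folded** surfaces can be unrolled into a flat sheet without stretching;
  every interior node has exactly four neighbours (e.g. parallel ridges);
* **deformed** surfaces require differential stretching and contain external
  corners (three neighbours) and/or internal corners (five neighbours), e.g.
  pillars, pits, bumps and real cell topographies.

Every builder here constructs its surface from a 2D integer height map: each
pixel ``(x, y)`` contributes a node at its height, and where 4-adjacent pixels
differ in height a vertical run of connector nodes is added on the higher
pixel's column, from the lower height up to one below the higher height, so
the surface is face-connected.  None of the modelled topographies has
overhangs, so the height-map representation is lossless.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .errors import InvalidSpecError

__all__ = [
    "SurfaceGraph",
    "build_flat",
    "build_from_height_map",
    "build_ridges",
    "build_pillars",
    "build_invaginations",
    "build_bumps",
    "build_quadrant_composite",
    "insert_defect",
    "classify_nodes",
    "flat_height_map",
    "ridges_height_map",
    "pillars_height_map",
    "invaginations_height_map",
    "bumps_height_map",
]

NodeLike = Sequence[int]


class SurfaceGraph:
    """An immutable set of surface nodes with face adjacency.

    Parameters
    ----------
    nodes
        ``(n, 3)`` integer array of ``(x, y, z)`` coordinates.  Duplicates are
        rejected; the node list is stored in lexicographic order.
    volume_shape
        Bounding volume ``(nx, ny, nz)``.  Inferred from the nodes if omitted.
    metadata
        Builder name and parameters; carried through serialization.
    height_map
        The generating height map (``heights[y, x]``), when the surface was
        built from one.  Kept so defects can be inserted by editing heights.
    """

    def __init__(
        self,
        nodes: np.ndarray | Iterable[NodeLike],
        volume_shape: Sequence[int] | None = None,
        metadata: Mapping | None = None,
        height_map: np.ndarray | None = None,
    ):
        nodes = np.asarray(nodes, dtype=np.int64)
        if nodes.ndim == 1 and nodes.size == 3:
            nodes = nodes[None, :]
        if nodes.ndim != 2 or nodes.shape[1] != 3 or nodes.shape[0] == 0:
            raise InvalidSpecError("nodes must be a non-empty (n, 3) integer array")
        if (nodes < 0).any():
            raise InvalidSpecError("node coordinates must be non-negative")
        order = np.lexsort((nodes[:, 2], nodes[:, 1], nodes[:, 0]))
        nodes = np.ascontiguousarray(nodes[order])
        if volume_shape is None:
            volume_shape = tuple(int(m) + 1 for m in nodes.max(axis=0))
        else:
            volume_shape = tuple(int(s) for s in volume_shape)
            if len(volume_shape) != 3 or any(s < 1 for s in volume_shape):
                raise InvalidSpecError(f"bad volume_shape {volume_shape}")
            if (nodes >= np.asarray(volume_shape)).any():
                raise InvalidSpecError("nodes fall outside volume_shape")
        self.nodes = nodes
        self.volume_shape = volume_shape
        self.metadata = dict(metadata or {})
        self.height_map = None if height_map is None else np.asarray(height_map)
        self._keys = self._ravel(nodes)
        if self._keys.size > 1 and (np.diff(self._keys) == 0).any():
            raise InvalidSpecError("duplicate nodes in surface")
        self._adjacency: sp.csr_matrix | None = None
        self.nodes.setflags(write=False)

    # -- basic protocol ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def __len__(self) -> int:
        return self.n_nodes

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        builder = self.metadata.get("builder", "custom")
        return (
            f"SurfaceGraph({self.n_nodes} nodes, volume={self.volume_shape}, "
            f"builder={builder!r})"
        )

    def same_nodes(self, other: "SurfaceGraph") -> bool:
        """True if both surfaces contain exactly the same node set."""
        return self.nodes.shape == other.nodes.shape and bool(
            np.array_equal(self.nodes, other.nodes)
        )

    def _ravel(self, nodes: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.volume_shape if hasattr(self, "volume_shape") else (0, 0, 0)
        # strides chosen so lexicographic node order == ascending key order
        return (nodes[:, 0] * ny + nodes[:, 1]) * nz + nodes[:, 2]

    def node_id(self, node: NodeLike | int) -> int:
        """Index of a node given as ``(x, y, z)``; integers pass through."""
        if np.isscalar(node) or isinstance(node, (int, np.integer)):
            i = int(node)
            if not 0 <= i < self.n_nodes:
                raise InvalidSpecError(f"node index {i} out of range")
            return i
        node = np.asarray(node, dtype=np.int64)
        if node.shape != (3,):
            raise InvalidSpecError(f"node must be an (x, y, z) triple, got {node!r}")
        if (node < 0).any() or (node >= np.asarray(self.volume_shape)).any():
            raise InvalidSpecError(f"node {tuple(node)} outside volume")
        key = (node[0] * self.volume_shape[1] + node[1]) * self.volume_shape[2] + node[2]
        i = int(np.searchsorted(self._keys, key))
        if i >= self.n_nodes or self._keys[i] != key:
            raise InvalidSpecError(f"node {tuple(node)} is not on the surface")
        return i

    def __contains__(self, node) -> bool:
        try:
            self.node_id(node)
            return True
        except InvalidSpecError:
            return False

    # -- adjacency ---------------------------------------------------------

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean face-adjacency matrix (CSR, float64 data of 1.0)."""
        if self._adjacency is None:
            self._adjacency = self._build_adjacency()
        return self._adjacency

    def _build_adjacency(self) -> sp.csr_matrix:
        n = self.n_nodes
        nx, ny, nz = self.volume_shape
        strides = (ny * nz, nz, 1)
        bounds = (nx, ny, nz)
        rows, cols = [], []
        for axis in range(3):
            movable = self.nodes[:, axis] + 1 < bounds[axis]
            src = np.flatnonzero(movable)
            cand = self._keys[src] + strides[axis]
            pos = np.searchsorted(self._keys, cand)
            ok = pos < n
            ok[ok] = self._keys[pos[ok]] == cand[ok]
            i, j = src[ok], pos[ok]
            rows.append(i)
            cols.append(j)
            rows.append(j)
            cols.append(i)
        row = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
        col = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        data = np.ones(row.size, dtype=np.float64)
        return sp.csr_matrix((data, (row, col)), shape=(n, n))

    @property
    def degrees(self) -> np.ndarray:
        """Number of face-adjacent surface neighbours per node."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, node: NodeLike | int) -> np.ndarray:
        """Node ids adjacent to ``node``."""
        i = self.node_id(node)
        A = self.adjacency
        return A.indices[A.indptr[i] : A.indptr[i + 1]].copy()

    def is_connected(self) -> bool:
        n_comp = csgraph.connected_components(self.adjacency, directed=False)[0]
        return n_comp == 1

    def degree_histogram(self) -> dict[int, int]:
        counts = np.bincount(self.degrees, minlength=7)
        return {int(d): int(c) for d, c in enumerate(counts) if c > 0}

    def interior_mask(self) -> np.ndarray:
        """Nodes whose (x, y) is strictly inside the lateral volume rim."""
        x, y = self.nodes[:, 0], self.nodes[:, 1]
        nx, ny, _ = self.volume_shape
        return (x > 0) & (x < nx - 1) & (y > 0) & (y < ny - 1)


def classify_nodes(surface: SurfaceGraph) -> tuple[np.ndarray, dict[int, int]]:
    """Per-node neighbour counts and their histogram.

    On flat and folded surfaces interior nodes have four neighbours; external
    corners (three) and internal corners (five) mark deformed topography.
    """
    degrees = surface.degrees
    return degrees, surface.degree_histogram()


# ---------------------------------------------------------------------------
# height-map machinery
# ---------------------------------------------------------------------------


def _validate_heights(heights: np.ndarray) -> np.ndarray:
    heights = np.asarray(heights)
    if heights.ndim != 2 or heights.size == 0:
        raise InvalidSpecError("height map must be a non-empty 2D array")
    if not np.issubdtype(heights.dtype, np.integer):
        if not np.allclose(heights, np.round(heights)):
            raise InvalidSpecError("height map must contain integers")
        heights = np.round(heights).astype(np.int64)
    else:
        heights = heights.astype(np.int64)
    if (heights < 0).any():
        raise InvalidSpecError("height map values must be non-negative")
    return heights


def build_from_height_map(
    heights: np.ndarray,
    volume_shape: Sequence[int] | None = None,
    metadata: Mapping | None = None,
) -> SurfaceGraph:
    """Convert a height-coded image into a continuous voxel surface.

    ``heights[y, x]`` gives the surface height at pixel ``(x, y)`` (row-major,
    origin top-left, matching single-channel microscopy height maps).  Each
    pixel contributes the node ``(x, y, h)``; where 4-adjacent pixels differ
    in height, vertical connector nodes are added on the higher pixel's column
    from the lower height up to ``h - 1``, which makes the surface a single
    face-connected sheet.  The connector convention ("attach to the higher
    pixel, include the lower endpoint") is recorded in the metadata.
    """
    heights = _validate_heights(heights)
    ny, nx = heights.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    tops = np.column_stack([xx.ravel(), yy.ravel(), heights.ravel()])

    # lowest 4-neighbour height per pixel (pixels at the image rim pad with
    # their own height, i.e. no connector toward the outside)
    pad = np.pad(heights, 1, mode="edge")
    nb_min = np.minimum.reduce(
        [pad[:-2, 1:-1], pad[2:, 1:-1], pad[1:-1, :-2], pad[1:-1, 2:]]
    )
    need = nb_min < heights
    if need.any():
        ys, xs = np.nonzero(need)
        lo = nb_min[need]
        cnt = (heights[need] - lo).astype(np.int64)  # z = lo .. h-1
        total = int(cnt.sum())
        rep = np.repeat(np.arange(cnt.size), cnt)
        start = np.concatenate([[0], np.cumsum(cnt)[:-1]])
        z = lo[rep] + (np.arange(total) - np.repeat(start, cnt))
        connectors = np.column_stack([xs[rep], ys[rep], z])
        nodes = np.vstack([tops, connectors])
    else:
        nodes = tops

    meta = dict(metadata or {})
    meta.setdefault("builder", "height_map")
    meta["connector_convention"] = "higher-pixel column, z in [lower, higher-1]"
    meta["height_map_shape"] = (int(ny), int(nx))
    if volume_shape is None:
        volume_shape = (nx, ny, int(heights.max()) + 1)
    return SurfaceGraph(nodes, volume_shape=volume_shape, metadata=meta, height_map=heights)


# ---------------------------------------------------------------------------
# height-map generators for the built-in topographies
# ---------------------------------------------------------------------------


def flat_height_map(width: int, height: int, z: int = 0) -> np.ndarray:
    if width < 1 or height < 1:
        raise InvalidSpecError(f"flat surface needs positive dimensions, got {width}x{height}")
    if z < 0:
        raise InvalidSpecError("flat surface height must be non-negative")
    return np.full((height, width), z, dtype=np.int64)


def ridges_height_map(
    extent: Sequence[int],
    ridge_height: int,
    ridge_width: int,
    spacing: int,
    orientation: str = "y",
    phase: int | None = None,
    base: int = 0,
) -> np.ndarray:
    """Parallel ridges of constant width/spacing on a flat base.

    Ridges extend along ``orientation`` and repeat with period
    ``ridge_width + spacing`` across the other axis.  ``phase`` is the column
    where a ridge begins (mod period); by default it is chosen so a gap is
    centred on the middle column, giving a natural "midway between two ridges"
    start position.
    """
    nx, ny = int(extent[0]), int(extent[1])
    if nx < 1 or ny < 1:
        raise InvalidSpecError("ridge field extent must be positive")
    if ridge_height < 0 or ridge_width < 1 or spacing < 0:
        raise InvalidSpecError(
            f"bad ridge geometry h={ridge_height} w={ridge_width} s={spacing}"
        )
    if orientation not in ("x", "y"):
        raise InvalidSpecError(f"orientation must be 'x' or 'y', got {orientation!r}")
    period = ridge_width + spacing
    across = nx if orientation == "y" else ny
    if period > across:
        raise InvalidSpecError("one ridge period does not fit in the extent")
    if phase is None:
        gap_start = across // 2 - (spacing - 1) // 2
        phase = (gap_start + spacing) % period
    cols = np.arange(across)
    on_ridge = (cols - phase) % period < ridge_width
    profile = np.where(on_ridge, base + ridge_height, base)
    if orientation == "y":
        return np.tile(profile, (ny, 1)).astype(np.int64)
    return np.tile(profile[:, None], (1, nx)).astype(np.int64)


def _hex_centers(extent, grid_spacing, footprint):
    """Pillar/pit centres on an offset-row ("hexagonal") grid.

    The square-lattice embedding uses rows spaced ``round(s * sqrt(3)/2)``
    with odd rows shifted by ``s // 2``.
    """
    nx, ny = extent
    row_pitch = max(1, round(grid_spacing * np.sqrt(3.0) / 2.0))
    half = footprint // 2
    centers = []
    r = 0
    y = half
    while y + half < ny:
        shift = (grid_spacing // 2) if (r % 2) else 0
        x = half + shift
        while x + half < nx:
            centers.append((x, y))
            x += grid_spacing
        y += row_pitch
        r += 1
    return centers, row_pitch


def _square_footprint(size: int, indent_corners: bool) -> np.ndarray:
    mask = np.ones((size, size), dtype=bool)
    if indent_corners and size >= 2:
        for cy in (0, size - 1):
            for cx in (0, size - 1):
                mask[cy, cx] = False
    return mask


def pillars_height_map(
    extent: Sequence[int],
    base_size: int = 5,
    pillar_height: int = 15,
    grid_spacing: int = 12,
    indent_corners: bool = True,
    base_z: int = 0,
) -> np.ndarray:
    """Square-based pillars (corner-indented) on an offset-row hexagonal grid."""
    nx, ny = int(extent[0]), int(extent[1])
    if base_size < 1 or pillar_height < 1 or grid_spacing < 1:
        raise InvalidSpecError("pillar geometry must be positive")
    row_pitch = max(1, round(grid_spacing * np.sqrt(3.0) / 2.0))
    if grid_spacing <= base_size or row_pitch <= base_size:
        raise InvalidSpecError("pillars overlap: grid spacing must exceed the base size")
    heights = np.full((ny, nx), base_z, dtype=np.int64)
    centers, _ = _hex_centers((nx, ny), grid_spacing, base_size)
    if not centers:
        raise InvalidSpecError("extent too small to place a single pillar")
    mask = _square_footprint(base_size, indent_corners)
    half = base_size // 2
    for cx, cy in centers:
        sub = heights[cy - half : cy - half + base_size, cx - half : cx - half + base_size]
        sub[mask] = base_z + pillar_height
    return heights


def invaginations_height_map(
    extent: Sequence[int],
    pit_size: int = 5,
    pit_depth: int = 15,
    grid_spacing: int = 12,
    indent_corners: bool = True,
) -> np.ndarray:
    """Square pits (inverted pillars) sunk into a raised base plane at z=depth."""
    inverted = pillars_height_map(
        extent,
        base_size=pit_size,
        pillar_height=pit_depth,
        grid_spacing=grid_spacing,
        indent_corners=indent_corners,
        base_z=0,
    )
    return (pit_depth - inverted).astype(np.int64)


def bumps_height_map(
    extent: Sequence[int],
    bump_height: int = 2,
    bump_size: int = 2,
    spacing: int = 2,
    base: int = 0,
) -> np.ndarray:
    """A dense regular grid of small square bumps (a highly deformed surface)."""
    nx, ny = int(extent[0]), int(extent[1])
    if bump_height < 1 or bump_size < 1 or spacing < 1:
        raise InvalidSpecError("bump geometry must be positive")
    period = bump_size + spacing
    xs = np.arange(nx)
    ys = np.arange(ny)
    on_x = (xs % period) < bump_size
    on_y = (ys % period) < bump_size
    heights = np.where(np.outer(on_y, on_x), base + bump_height, base)
    return heights.astype(np.int64)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_flat(width: int, height: int, z: int = 0) -> SurfaceGraph:
    """A flat horizontal sheet of ``width`` x ``height`` nodes at height ``z``."""
    hm = flat_height_map(width, height, z)
    return build_from_height_map(
        hm, metadata={"builder": "flat", "width": int(width), "height": int(height), "z": int(z)}
    )


def build_ridges(
    extent: Sequence[int],
    ridge_height: int,
    ridge_width: int,
    spacing: int,
    orientation: str = "y",
    phase: int | None = None,
    base: int = 0,
    volume_shape: Sequence[int] | None = None,
) -> SurfaceGraph:
    """A folded surface of uniformly sized and spaced parallel ridges.

    With ``ridge_height=0`` the output is node-for-node identical to
    :func:`build_flat`.  For positive heights every interior node has exactly
    four neighbours — the defining property of a folded surface — and the
    sheet unrolls to a flat one with period ``ridge_width + spacing +
    2*ridge_height`` across the ridges.

    Widths below 3 are degenerate in a one-node-thick sheet: the two walls of
    the ridge occupy adjacent (width 2) or the same (width 1) columns, which
    welds them together at the base and breaks the folded property.  Such
    fins are permitted (a height map is what it is) but are not folded
    surfaces.
    """
    hm = ridges_height_map(extent, ridge_height, ridge_width, spacing, orientation, phase, base)
    period = ridge_width + spacing
    across = extent[0] if orientation == "y" else extent[1]
    if phase is None:
        gap_start = across // 2 - (spacing - 1) // 2
        phase = (gap_start + spacing) % period
    meta = {
        "builder": "ridges",
        "extent": (int(extent[0]), int(extent[1])),
        "ridge_height": int(ridge_height),
        "ridge_width": int(ridge_width),
        "spacing": int(spacing),
        "orientation": orientation,
        "phase": int(phase),
        "base": int(base),
    }
    return build_from_height_map(hm, volume_shape=volume_shape, metadata=meta)


def build_pillars(
    extent: Sequence[int],
    base_size: int = 5,
    pillar_height: int = 15,
    grid_spacing: int = 12,
    indent_corners: bool = True,
    base_z: int = 0,
) -> SurfaceGraph:
    """A deformed surface with flat-topped pillars on a hexagonal grid."""
    hm = pillars_height_map(extent, base_size, pillar_height, grid_spacing, indent_corners, base_z)
    meta = {
        "builder": "pillars",
        "extent": (int(extent[0]), int(extent[1])),
        "base_size": int(base_size),
        "pillar_height": int(pillar_height),
        "grid_spacing": int(grid_spacing),
        "indent_corners": bool(indent_corners),
        "base_z": int(base_z),
    }
    return build_from_height_map(hm, metadata=meta)


def build_invaginations(
    extent: Sequence[int],
    pit_size: int = 5,
    pit_depth: int = 15,
    grid_spacing: int = 12,
    indent_corners: bool = True,
) -> SurfaceGraph:
    """A deformed surface with square pits sunk into a raised plane."""
    hm = invaginations_height_map(extent, pit_size, pit_depth, grid_spacing, indent_corners)
    meta = {
        "builder": "invaginations",
        "extent": (int(extent[0]), int(extent[1])),
        "pit_size": int(pit_size),
        "pit_depth": int(pit_depth),
        "grid_spacing": int(grid_spacing),
        "indent_corners": bool(indent_corners),
    }
    return build_from_height_map(hm, metadata=meta)


def build_bumps(
    extent: Sequence[int],
    bump_height: int = 2,
    bump_size: int = 2,
    spacing: int = 2,
    base: int = 0,
) -> SurfaceGraph:
    hm = bumps_height_map(extent, bump_height, bump_size, spacing, base)
    meta = {
        "builder": "bumps",
        "extent": (int(extent[0]), int(extent[1])),
        "bump_height": int(bump_height),
        "bump_size": int(bump_size),
        "spacing": int(spacing),
        "base": int(base),
    }
    return build_from_height_map(hm, metadata=meta)


def build_quadrant_composite(
    upper_left: np.ndarray,
    upper_right: np.ndarray,
    lower_left: np.ndarray,
    lower_right: np.ndarray,
) -> SurfaceGraph:
    """Stitch four equally sized quadrant height maps into one surface.

    The four quadrants must agree on the height of the shared central corner
    pixel so that the meeting point is a well-defined start node; any height
    steps along the seams are bridged by vertical connector nodes, so the
    composite is a single connected surface through which probability is
    exchanged across quadrant boundaries.
    """
    quads = [np.asarray(_validate_heights(q)) for q in
             (upper_left, upper_right, lower_left, lower_right)]
    shape = quads[0].shape
    if any(q.shape != shape for q in quads):
        raise InvalidSpecError("all four quadrants must have the same shape")
    corners = [quads[0][-1, -1], quads[1][-1, 0], quads[2][0, -1], quads[3][0, 0]]
    if len(set(int(c) for c in corners)) != 1:
        raise InvalidSpecError(
            f"quadrants disagree on the shared central corner height: {corners}"
        )
    hm = np.block([[quads[0], quads[1]], [quads[2], quads[3]]])
    meta = {"builder": "quadrant_composite", "quadrant_shape": tuple(int(s) for s in shape)}
    return build_from_height_map(hm, metadata=meta)


# ---------------------------------------------------------------------------
# defects
# ---------------------------------------------------------------------------


def insert_defect(
    surface: SurfaceGraph,
    kind: str,
    position: Sequence[int],
    depth: int = 1,
) -> SurfaceGraph:
    """Cut a one-node-wide slot or notch through a ridge.

    A *slot* removes the ridge down to its base at one row, opening a
    full-height corridor whose base corners are internal corners with five
    neighbours; a *notch* removes ``depth`` nodes (default one) from the top
    of the ridge at one row.  ``position`` is an ``(x, y)`` (a trailing ``z``
    is ignored) that must lie on a ridge; the cut spans the full ridge width
    at that row.  The input surface is unchanged; a new surface is returned.
    """
    if kind not in ("slot", "notch"):
        raise InvalidSpecError(f"defect kind must be 'slot' or 'notch', got {kind!r}")
    if surface.height_map is None or surface.metadata.get("builder") != "ridges":
        raise InvalidSpecError("defects can only be inserted into a ridge surface")
    meta = surface.metadata
    orientation = meta["orientation"]
    phase, width, spacing = meta["phase"], meta["ridge_width"], meta["spacing"]
    base = meta["base"]
    period = width + spacing
    x, y = int(position[0]), int(position[1])

    hm = surface.height_map.copy()
    if orientation == "x":  # normalize: columns run across the ridges
        hm = hm.T
        x, y = y, x
    ny, nx = hm.shape
    if not (0 <= x < nx and 0 <= y < ny):
        raise InvalidSpecError(f"defect position {(x, y)} outside the surface extent")
    offset = (x - phase) % period
    if offset >= width:
        raise InvalidSpecError(f"defect position {(x, y)} is not on a ridge")
    if depth < 1:
        raise InvalidSpecError("defect depth must be >= 1")

    start_col = x - offset
    cols = slice(max(start_col, 0), min(start_col + width, nx))
    if kind == "slot":
        hm[y, cols] = base
    else:
        hm[y, cols] = np.maximum(base, hm[y, cols] - depth)

    if orientation == "x":
        hm = hm.T
    new_meta = dict(meta)
    new_meta["defect"] = {"kind": kind, "position": (int(position[0]), int(position[1])),
                          "depth": int(depth)}
    return build_from_height_map(hm, volume_shape=surface.volume_shape, metadata=new_meta)
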