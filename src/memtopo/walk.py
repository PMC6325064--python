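"""Lazy random walk on a surface graph.

Diffusion is simulated as a discrete lazy random walk: at every iteration a
particle stays where it is with probability 0.5 and otherwise moves to one of
its face-adjacent surface neighbours, chosen uniformly.  For the bulk case of
four neighbours the probability of a move to a particular neighbour is hence
0.125.  The same process is run in two forms:

* **probability propagation** — the full distribution ``u`` over nodes is
  advanced by the column-stochastic operator ``u_{t+1} = D u_t`` with
  ``D(i, i) = 0.5`` and ``D(i, j) = 0.5 / deg(j)`` for adjacent ``i, j``
  (mass leaving a node splits equally among its neighbours, so total mass is
  conserved on irregular graphs).  This covers every possible path at once
  and eliminates sampling noise;
* **single-particle tracks** — stochastic realizations of the same walk,
  reproducible from a seed, for comparison with experimental-style data.

Because the support of the distribution can only grow by one hop per
iteration, long runs on large surfaces restrict the operator to an expanding
region around the start node (a prefix of the nodes ordered by hop distance).
The restriction is exact, not approximate: at iteration ``t`` the region
always contains the full hop-ball of radius ``t``, so restricted and
full-graph propagation agree to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .distances import geodesic_transform
from .errors import ContractError, InvalidSpecError
from .surfaces import SurfaceGraph

__all__ = [
    "ProbabilityField",
    "WalkOperator",
    "TrackSet",
    "transition_matrix",
    "step",
    "propagate",
    "propagate_time_course",
    "sample_tracks",
]

P_MOVE = 0.5  # lazy-walk move probability; time is measured in iterations


def transition_matrix(surface: SurfaceGraph) -> sp.csr_matrix:
    """The column-stochastic lazy-walk operator ``D`` for a surface.

    Isolated nodes (degree zero) keep all their mass.
    """
    A = surface.adjacency
    deg = surface.degrees.astype(np.float64)
    inv = np.zeros_like(deg)
    np.divide(P_MOVE, deg, out=inv, where=deg > 0)
    off = A @ sp.diags(inv)  # off[i, j] = 0.5 / deg(j) for j adjacent to i
    self_weight = np.where(deg > 0, 1.0 - P_MOVE, 1.0)
    return (off + sp.diags(self_weight)).tocsr()


class WalkOperator:
    """Surface-bound lazy-walk operator (thin wrapper around the CSR matrix)."""

    def __init__(self, surface: SurfaceGraph):
        self.surface = surface
        self.p_move = P_MOVE
        self.matrix = transition_matrix(surface)

    def __call__(self, mass: np.ndarray) -> np.ndarray:
        return self.matrix @ mass


@dataclass
class ProbabilityField:
    """Per-node probability mass at one iteration of the walk."""

    surface: SurfaceGraph
    mass: np.ndarray
    iteration: int
    origin: int  # node id of the start node

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if self.mass.shape != (self.surface.n_nodes,):
            raise ContractError(
                f"mass vector length {self.mass.shape} does not match surface "
                f"({self.surface.n_nodes} nodes)"
            )

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @classmethod
    def point_mass(cls, surface: SurfaceGraph, start) -> "ProbabilityField":
        sid = surface.node_id(start)
        mass = np.zeros(surface.n_nodes)
        mass[sid] = 1.0
        return cls(surface=surface, mass=mass, iteration=0, origin=sid)

    def to_frame(self, drop_zero: bool = True) -> pd.DataFrame:
        nodes = self.surface.nodes
        df = pd.DataFrame(
            {"x": nodes[:, 0], "y": nodes[:, 1], "z": nodes[:, 2], "mass": self.mass}
        )
        return df[df["mass"] > 0].reset_index(drop=True) if drop_zero else df


def step(field: ProbabilityField, op: WalkOperator | None = None) -> ProbabilityField:
    """Advance the probability field by one lazy-walk iteration."""
    if op is None:
        op = WalkOperator(field.surface)
    elif op.surface is not field.surface and not op.surface.same_nodes(field.surface):
        raise ContractError("operator and field are bound to different surfaces")
    return ProbabilityField(
        surface=field.surface,
        mass=op.matrix @ field.mass,
        iteration=field.iteration + 1,
        origin=field.origin,
    )


# ---------------------------------------------------------------------------
# the propagation engine
# ---------------------------------------------------------------------------


def _run_walk(
    surface: SurfaceGraph,
    start,
    n_iterations: int,
    visit: Callable[[int, np.ndarray, np.ndarray, int], None],
    expanding: bool = True,
    margin: int = 64,
) -> None:
    """Drive the walk, calling ``visit(t, mass_prefix, order, k)`` each step.

    ``order`` permutes node ids by hop distance from the start; at any call
    the mass of node ``order[i]`` is ``mass_prefix[i]`` for ``i < k`` and
    exactly zero beyond.  With ``expanding=False`` the permutation is the
    identity and ``k`` is the node count.
    """
    if n_iterations < 0:
        raise InvalidSpecError("n_iterations must be non-negative")
    start_id = surface.node_id(start)
    D = transition_matrix(surface)
    n = surface.n_nodes

    if not expanding:
        order = np.arange(n, dtype=np.int64)
        u = np.zeros(n)
        u[start_id] = 1.0
        visit(0, u, order, n)
        for t in range(1, n_iterations + 1):
            u = D @ u
            visit(t, u, order, n)
        return

    hops = geodesic_transform(surface, start_id)
    order = np.argsort(hops, kind="stable")  # unreachable (inf) sorted last
    sorted_hops = hops[order]
    reach = int(np.isfinite(sorted_hops).sum())
    inv = np.empty(n, dtype=np.int64)
    inv[order] = np.arange(n, dtype=np.int64)
    C = D.tocoo()
    P = sp.csr_matrix((C.data, (inv[C.row], inv[C.col])), shape=(n, n))

    margin = max(1, int(margin))
    radius = margin
    k = min(int(np.searchsorted(sorted_hops, radius, side="right")), reach)
    Pk = P[:k, :k]
    u = np.zeros(k)
    u[0] = 1.0  # order[0] is the start node (hop distance 0)
    visit(0, u, order, k)
    for t in range(1, n_iterations + 1):
        if t > radius and k < reach:
            radius = t + margin
            k_new = min(int(np.searchsorted(sorted_hops, radius, side="right")), reach)
            if k_new > k:
                Pk = P[:k_new, :k_new]
                u = np.concatenate([u, np.zeros(k_new - k)])
                k = k_new
        elif t > radius:
            radius = t + margin
        u = Pk @ u
        visit(t, u, order, k)


def propagate(
    surface: SurfaceGraph,
    start,
    n_iterations: int,
    record_every: int | None = 1,
    record_iterations: Sequence[int] | None = None,
    expanding: bool = True,
    margin: int = 64,
) -> list[ProbabilityField]:
    """Propagate a point mass and return snapshots of the distribution.

    Snapshots are taken every ``record_every`` iterations (the final iteration
    is always recorded), or exactly at ``record_iterations`` if given.
    """
    start_id = surface.node_id(start)
    if record_iterations is not None:
        wanted = set(int(t) for t in record_iterations)
        if any(t < 0 or t > n_iterations for t in wanted):
            raise InvalidSpecError("record_iterations outside the simulated range")
    else:
        if record_every is None or record_every < 1:
            raise InvalidSpecError("record_every must be a positive integer")
        wanted = set(range(0, n_iterations + 1, int(record_every)))
        wanted.add(n_iterations)

    fields: list[ProbabilityField] = []

    def visit(t, u, order, k):
        if t in wanted:
            full = np.zeros(surface.n_nodes)
            full[order[:k]] = u
            fields.append(
                ProbabilityField(surface=surface, mass=full, iteration=t, origin=start_id)
            )

    _run_walk(surface, start_id, n_iterations, visit, expanding=expanding, margin=margin)
    return fields


def propagate_time_course(
    surface: SurfaceGraph,
    start,
    n_iterations: int,
    observables: Mapping[str, np.ndarray | Callable[[np.ndarray], float]],
    expanding: bool = True,
    margin: int = 64,
) -> dict[str, np.ndarray]:
    """Record per-iteration summaries of the walk without storing snapshots.

    Each observable is either a per-node weight vector ``w`` (recording
    ``sum_i w_i * u_i(t)``, e.g. a squared distance map for an MSD time
    course) or a callable applied to the vector of currently active masses
    (inactive nodes hold exactly zero mass).  Returns ``{"iteration": 0..n,
    name: series}``.
    """
    out = {name: np.empty(n_iterations + 1) for name in observables}
    permuted: dict[str, np.ndarray] = {}

    def visit(t, u, order, k):
        for name, obs in observables.items():
            if callable(obs):
                out[name][t] = obs(u)
            else:
                if name not in permuted:
                    w = np.asarray(obs, dtype=np.float64)
                    if w.shape != (surface.n_nodes,):
                        raise ContractError(
                            f"observable {name!r} length {w.shape} does not match surface"
                        )
                    permuted[name] = w[order]
                out[name][t] = permuted[name][:k] @ u

    _run_walk(surface, start, n_iterations, visit, expanding=expanding, margin=margin)
    out["iteration"] = np.arange(n_iterations + 1)
    return out


# ---------------------------------------------------------------------------
# single-particle tracks
# ---------------------------------------------------------------------------


@dataclass
class TrackSet:
    """Sampled single-particle trajectories on a surface.

    ``node_ids[i, t]`` is the node id of track ``i`` at iteration ``t``.
    Consecutive entries are either identical (no move) or face-adjacent.
    """

    surface: SurfaceGraph
    node_ids: np.ndarray  # (n_tracks, n_iterations + 1)
    origin: int
    seed: int

    @property
    def n_tracks(self) -> int:
        return self.node_ids.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.node_ids.shape[1] - 1

    def coords(self) -> np.ndarray:
        """Track coordinates, shape ``(n_tracks, n_iterations + 1, 3)``."""
        return self.surface.nodes[self.node_ids]

    def to_frame(self) -> pd.DataFrame:
        n_tr, n_it = self.node_ids.shape
        coords = self.coords().reshape(-1, 3)
        return pd.DataFrame(
            {
                "track_id": np.repeat(np.arange(n_tr), n_it),
                "iteration": np.tile(np.arange(n_it), n_tr),
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
            }
        )


def sample_tracks(
    surface: SurfaceGraph,
    start,
    n_tracks: int,
    n_iterations: int,
    seed: int,
) -> TrackSet:
    """Sample lazy-walk trajectories (reproducible from the seed).

    Each iteration every particle stays put with probability 0.5, otherwise
    it hops to a uniformly chosen surface neighbour.  The empirical occupancy
    over many tracks converges to the propagated probability field.
    """
    if n_tracks < 1:
        raise InvalidSpecError("n_tracks must be >= 1")
    if n_iterations < 0:
        raise InvalidSpecError("n_iterations must be non-negative")
    start_id = surface.node_id(start)
    rng = np.random.default_rng(seed)
    A = surface.adjacency
    indptr, indices = A.indptr, A.indices
    deg = surface.degrees

    ids = np.empty((n_tracks, n_iterations + 1), dtype=np.int64)
    cur = np.full(n_tracks, start_id, dtype=np.int64)
    ids[:, 0] = cur
    for t in range(1, n_iterations + 1):
        moving = rng.random(n_tracks) < P_MOVE
        moving &= deg[cur] > 0
        if moving.any():
            src = cur[moving]
            pick = rng.integers(0, deg[src])
            cur = cur.copy()
            cur[moving] = indices[indptr[src] + pick]
        ids[:, t] = cur
    return TrackSet(surface=surface, node_ids=ids, origin=start_id, seed=int(seed))
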