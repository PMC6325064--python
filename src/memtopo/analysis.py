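"""MSD, diffusion-coefficient and D_rel analysis of simulated diffusion.

The population mean squared displacement at iteration ``t`` is the
mass-weighted squared distance from the start node,

    MSD_metric(t) = sum_nodes u_t(node) * d_metric(node)^2,

computed for the 2D Euclidean, 3D Euclidean and shortest-within-surface
(SWSD) distance maps.  On a flat surface the walk is Brownian and the
Euclidean MSD grows as ``0.5 t`` (half the particles move one unit per
iteration); the SWSD MSD is larger by a factor approaching ``1 + 2/pi``
because the city-block distance |dx| + |dy| overstates the straight line.

``D_rel`` factors out these metric-intrinsic offsets: it divides the MSD on
the test surface by the MSD of the *same* metric at the same iteration on a
flat baseline surface.  ``D_rel = 1`` is apparent Brownian motion; values
above/below 1 are apparent super-/subdiffusion, which surface topography
alone can produce.  ``D_rel`` is a per-iteration MSD ratio (not a ratio of
fitted slopes), so transient phases — a superdiffusive peak when a shortcut
opens extra area to the diffusion front, the later crossing below 1 when the
shortcut understates the distance actually travelled — remain visible as a
function of iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMaps, compute_distance_maps, normalize_metric
from .errors import ContractError, InvalidSpecError
from .surfaces import SurfaceGraph, build_flat
from .walk import ProbabilityField, TrackSet, propagate_time_course

__all__ = [
    "MSDSeries",
    "DrelCurve",
    "DiffusionFit",
    "AnomalySummary",
    "population_msd",
    "msd_time_course",
    "flat_baseline_msd",
    "drel",
    "fit_diffusion",
    "classify_anomaly",
    "occupied_node_count",
    "probability_by_distance",
    "track_msd",
]

FLAT_SWSD_TO_2D = 1.0 + 2.0 / np.pi  # large-t MSD ratio of city-block to straight line


def _sq_weights(maps: DistanceMaps) -> dict[str, np.ndarray]:
    out = {}
    for name in ("2d", "3d", "swsd"):
        d = maps.metric(name)
        out[name] = np.where(np.isfinite(d), d, 0.0) ** 2  # unreachable: mass is 0 anyway
    return out


@dataclass
class MSDSeries:
    """Per-iteration population MSD for the three metrics (node^2 units)."""

    iterations: np.ndarray
    msd_2d: np.ndarray
    msd_3d: np.ndarray
    msd_swsd: np.ndarray
    provenance: dict = field(default_factory=dict)

    def metric(self, name: str) -> np.ndarray:
        key = normalize_metric(name)
        return {"2d": self.msd_2d, "3d": self.msd_3d, "swsd": self.msd_swsd}[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "msd_2d": self.msd_2d,
                "msd_3d": self.msd_3d,
                "msd_swsd": self.msd_swsd,
            }
        )


@dataclass
class DrelCurve:
    """MSD on a test surface divided by the same-metric flat-surface MSD."""

    iterations: np.ndarray
    drel_2d: np.ndarray
    drel_3d: np.ndarray
    drel_swsd: np.ndarray
    provenance: dict = field(default_factory=dict)

    def metric(self, name: str) -> np.ndarray:
        key = normalize_metric(name)
        return {"2d": self.drel_2d, "3d": self.drel_3d, "swsd": self.drel_swsd}[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "drel_2d": self.drel_2d,
                "drel_3d": self.drel_3d,
                "drel_swsd": self.drel_swsd,
            }
        )


@dataclass
class DiffusionFit:
    """Least-squares tangent to MSD(t): slope is the diffusion rate (node^2/iter)."""

    slope: float
    intercept: float
    window: tuple[int, int]
    r_squared: float
    metric: str


@dataclass
class AnomalySummary:
    """Interval labels and landmarks of a D_rel curve for one metric."""

    iterations: np.ndarray
    labels: np.ndarray  # 'super' | 'normal' | 'sub' per iteration
    tolerance: float
    metric: str
    argmax_iteration: int
    max_value: float
    argmin_iteration: int
    min_value: float
    return_iteration: int | None  # first crossing of 1 after the initial peak


# ---------------------------------------------------------------------------
# MSD computation
# ---------------------------------------------------------------------------


def population_msd(fields: Sequence[ProbabilityField], maps: DistanceMaps) -> MSDSeries:
    """MSD of recorded probability snapshots, for all three metrics."""
    fields = sorted(fields, key=lambda f: f.iteration)
    if not fields:
        raise ContractError("no probability fields given")
    surface = maps.surface
    for f in fields:
        if f.surface is not surface and not f.surface.same_nodes(surface):
            raise ContractError("fields and distance maps come from different surfaces")
        if f.origin != maps.start:
            raise ContractError("fields and distance maps have different start nodes")
    w = _sq_weights(maps)
    its = np.array([f.iteration for f in fields])
    series = {name: np.array([float(f.mass @ w[name]) for f in fields]) for name in w}
    return MSDSeries(
        iterations=its,
        msd_2d=series["2d"],
        msd_3d=series["3d"],
        msd_swsd=series["swsd"],
        provenance={"start": maps.start_node, "surface": surface.metadata.get("builder")},
    )


def msd_time_course(
    surface: SurfaceGraph,
    start,
    n_iterations: int,
    maps: DistanceMaps | None = None,
    expanding: bool = True,
) -> MSDSeries:
    """Propagate from ``start`` and record the MSD at every iteration.

    Memory-light alternative to snapshotting: only three weighted sums are
    kept per iteration.
    """
    if maps is None:
        maps = compute_distance_maps(surface, start)
    elif maps.start != surface.node_id(start):
        raise ContractError("distance maps were computed from a different start node")
    w = _sq_weights(maps)
    tc = propagate_time_course(
        surface, start, n_iterations,
        observables={"2d": w["2d"], "3d": w["3d"], "swsd": w["swsd"]},
        expanding=expanding,
    )
    return MSDSeries(
        iterations=tc["iteration"],
        msd_2d=tc["2d"],
        msd_3d=tc["3d"],
        msd_swsd=tc["swsd"],
        provenance={"start": maps.start_node, "surface": surface.metadata.get("builder")},
    )


def flat_baseline_msd(n_iterations: int, halfwidth: int | None = None, z: int = 0) -> MSDSeries:
    """MSD time course on a flat surface, for use as the D_rel denominator.

    The sheet half-width defaults to ``4 * sqrt(t) + 8`` nodes, i.e. eight
    per-axis standard deviations of the iteration-``t`` distribution, so the
    mass that could feel the rim is < 1e-26 of the total and the baseline is
    indistinguishable from an unbounded sheet at every tolerance used here.
    """
    if halfwidth is None:
        halfwidth = int(np.ceil(4.0 * np.sqrt(max(n_iterations, 1)))) + 8
    size = 2 * halfwidth + 1
    surface = build_flat(size, size, z=z)
    start = (halfwidth, halfwidth, z)
    series = msd_time_course(surface, start, n_iterations)
    series.provenance.update({"baseline": "flat", "halfwidth": halfwidth})
    return series


def drel(test: MSDSeries, baseline_flat: MSDSeries) -> DrelCurve:
    """Per-iteration MSD ratio against a same-metric flat baseline.

    Iteration 0 is excluded (0/0).  The iteration grids must match.
    """
    if not np.array_equal(test.iterations, baseline_flat.iterations):
        raise ContractError("test and baseline series are on different iteration grids")
    keep = test.iterations > 0
    its = test.iterations[keep]
    ratios = {}
    for name in ("2d", "3d", "swsd"):
        denom = baseline_flat.metric(name)[keep]
        if (denom <= 0).any():
            raise ContractError("flat baseline MSD vanishes at a positive iteration")
        ratios[name] = test.metric(name)[keep] / denom
    return DrelCurve(
        iterations=its,
        drel_2d=ratios["2d"],
        drel_3d=ratios["3d"],
        drel_swsd=ratios["swsd"],
        provenance={"test": test.provenance, "baseline": baseline_flat.provenance},
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def fit_diffusion(
    series: MSDSeries,
    metric: str = "2d",
    window: tuple[int, int] | None = None,
) -> DiffusionFit:
    """Ordinary least-squares tangent to MSD vs iteration over a window.

    ``window`` is an inclusive ``(t_lo, t_hi)`` iteration range; the default
    is the last half of the series.  The slope is the diffusion rate in
    node^2 per iteration (0.5 for the lazy walk on a flat surface, Euclidean
    metrics).
    """
    key = normalize_metric(metric)
    t = np.asarray(series.iterations, dtype=np.float64)
    y = series.metric(key)
    if window is None:
        lo = t[len(t) // 2]
        window = (int(lo), int(t[-1]))
    t_lo, t_hi = window
    mask = (t >= t_lo) & (t <= t_hi)
    if mask.sum() < 2:
        raise ContractError(f"fit window {window} selects fewer than two points")
    slope, intercept = np.polyfit(t[mask], y[mask], 1)
    resid = y[mask] - (slope * t[mask] + intercept)
    ss_tot = float(((y[mask] - y[mask].mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(
        slope=float(slope),
        intercept=float(intercept),
        window=(int(t_lo), int(t_hi)),
        r_squared=r2,
        metric=key,
    )


def classify_anomaly(
    curve: DrelCurve,
    metric: str = "swsd",
    tolerance: float = 0.01,
) -> AnomalySummary:
    """Label each iteration super/normal/sub and locate the curve landmarks.

    ``super`` where D_rel > 1 + tolerance, ``sub`` where D_rel < 1 -
    tolerance, ``normal`` otherwise.  Landmarks are read from the raw curve
    with ties broken to the earliest iteration: the global maximum, the
    global minimum, and the first iteration after the maximum at which the
    curve falls back to or below 1 (``None`` if it never does).
    """
    if tolerance <= 0:
        raise InvalidSpecError("tolerance must be positive")
    key = normalize_metric(metric)
    v = curve.metric(key)
    its = curve.iterations
    labels = np.full(v.shape, "normal", dtype=object)
    labels[v > 1.0 + tolerance] = "super"
    labels[v < 1.0 - tolerance] = "sub"
    imax = int(np.argmax(v))
    imin = int(np.argmin(v))
    if v[imax] > 1.0:
        after = np.flatnonzero(v[imax + 1 :] <= 1.0)
        ret = int(its[imax + 1 + after[0]]) if after.size else None
    else:
        ret = None  # no super phase, nothing to return from
    return AnomalySummary(
        iterations=its,
        labels=labels,
        tolerance=float(tolerance),
        metric=key,
        argmax_iteration=int(its[imax]),
        max_value=float(v[imax]),
        argmin_iteration=int(its[imin]),
        min_value=float(v[imin]),
        return_iteration=ret,
    )


def occupied_node_count(
    fields: Sequence[ProbabilityField], threshold: float = 0.0
) -> pd.DataFrame:
    """Number of nodes carrying mass above ``threshold``, per snapshot.

    On surfaces without absorbing boundaries the count is non-decreasing;
    defects that open shortcuts let the front claim nodes faster.
    """
    if threshold < 0:
        raise InvalidSpecError("threshold must be >= 0")
    fields = sorted(fields, key=lambda f: f.iteration)
    its = [f.iteration for f in fields]
    counts = [int((f.mass > threshold).sum()) for f in fields]
    return pd.DataFrame({"iteration": its, "occupied": counts})


def probability_by_distance(
    field: ProbabilityField, maps: DistanceMaps, metric: str = "swsd"
) -> pd.Series:
    """Summed mass per integer distance shell (``floor(d)`` binning).

    The shells partition the surface, so the histogram sums to the total
    mass.  SWSD distances are integers already, so no mass straddles a shell.
    """
    key = normalize_metric(metric)
    if field.origin != maps.start:
        raise ContractError("field and distance maps have different start nodes")
    d = maps.metric(key)
    finite = np.isfinite(d)
    shells = np.floor(d[finite]).astype(np.int64)
    mass = field.mass[finite]
    sums = np.bincount(shells, weights=mass)
    return pd.Series(sums, index=pd.RangeIndex(len(sums), name="shell"), name=f"mass_{key}")


def track_msd(tracks: TrackSet, maps: DistanceMaps, metric: str = "2d") -> pd.DataFrame:
    """Empirical ensemble MSD of sampled tracks, with its standard error."""
    key = normalize_metric(metric)
    if tracks.origin != maps.start:
        raise ContractError("tracks and distance maps have different start nodes")
    d = maps.metric(key)
    sq = np.where(np.isfinite(d), d, 0.0)[tracks.node_ids] ** 2
    msd = sq.mean(axis=0)
    sem = sq.std(axis=0, ddof=1) / np.sqrt(tracks.n_tracks)
    return pd.DataFrame(
        {"iteration": np.arange(tracks.n_iterations + 1), "msd": msd, "sem": sem}
    )
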