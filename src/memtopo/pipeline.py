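"""End-to-end run orchestration: build -> propagate -> distances -> analyze.

A :class:`RunConfig` names a surface (catalog fixture or serialized file), a
start node, an iteration budget and an output directory; :func:`run_pipeline`
executes the stages, writes every table and image, and finishes with a
manifest of checksums so deterministic configurations reproduce bit-identical
output trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, io
from .distances import compute_distance_maps
from .errors import InvalidSpecError, StageError
from .fixtures import generate_fixture
from .walk import propagate, sample_tracks

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """What to run and where to put the results."""

    out_dir: str | Path
    fixture: str | None = None
    fixture_overrides: dict = field(default_factory=dict)
    surface_path: str | Path | None = None
    start: str | tuple = "default"
    n_iterations: int = 256
    record_every: int | None = None  # snapshot cadence; None -> n_iterations // 4
    baseline_halfwidth: int | None = None
    anomaly_tolerance: float = 0.01
    n_tracks: int = 0  # optionally also sample this many tracks
    seed: int | None = None  # required when n_tracks > 0
    expanding: bool = True

    def validate(self) -> None:
        if (self.fixture is None) == (self.surface_path is None):
            raise InvalidSpecError("specify exactly one of fixture / surface_path")
        if self.surface_path is not None and not Path(self.surface_path).exists():
            raise InvalidSpecError(f"surface file not found: {self.surface_path}")
        if self.n_iterations < 1:
            raise InvalidSpecError("n_iterations must be >= 1")
        if self.n_tracks > 0 and self.seed is None:
            raise InvalidSpecError("a seed is required to sample tracks")


def _resolve_surface(config: RunConfig):
    if config.fixture is not None:
        fx = generate_fixture(config.fixture, **config.fixture_overrides)
        surface, starts = fx.surface, fx.starts
    else:
        surface, starts = io.load_surface(config.surface_path), {}
    if isinstance(config.start, str):
        if config.start not in starts:
            raise InvalidSpecError(
                f"start preset {config.start!r} unknown; presets: {sorted(starts)}"
            )
        start = starts[config.start]
    else:
        start = tuple(int(c) for c in config.start)
    return surface, start


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dictionary.

    Any stage failure raises :class:`StageError` labelled with the stage name;
    partial outputs written before the failure are left in place with a
    ``INCOMPLETE`` marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    written: list[Path] = []
    stage = "surface"
    try:
        surface, start = _resolve_surface(config)
        written.append(io.save_surface(surface, out / "surface.csv"))

        stage = "distances"
        maps = compute_distance_maps(surface, start)
        written.append(out / "distances.csv")
        maps.to_frame().to_csv(written[-1], index=False)

        stage = "simulate"
        series = analysis.msd_time_course(
            surface, start, config.n_iterations, maps=maps, expanding=config.expanding
        )
        cadence = config.record_every or max(1, config.n_iterations // 4)
        snapshots = propagate(
            surface, start, config.n_iterations, record_every=cadence,
            expanding=config.expanding,
        )
        for snap in snapshots:
            img = io.zproject(snap)
            written.append(
                io.write_projection_tiff(img, out / f"projection_t{snap.iteration:06d}.tif")
            )
        written.append(io.write_probability_csv(snapshots[-1], out / "final_field.csv"))

        stage = "baseline"
        baseline = analysis.flat_baseline_msd(
            config.n_iterations, halfwidth=config.baseline_halfwidth
        )

        stage = "analyze"
        written.append(out / "msd.csv")
        series.to_frame().to_csv(written[-1], index=False)
        curve = analysis.drel(series, baseline)
        written.append(out / "drel.csv")
        curve.to_frame().to_csv(written[-1], index=False)

        report: dict = {
            "surface": surface.metadata.get("builder"),
            "n_nodes": surface.n_nodes,
            "start": [int(c) for c in surface.nodes[maps.start]],
            "n_iterations": int(config.n_iterations),
            "metrics": {},
        }
        tail = max(1, len(curve.iterations) // 10)
        for metric in ("2d", "3d", "swsd"):
            summary = analysis.classify_anomaly(
                curve, metric=metric, tolerance=config.anomaly_tolerance
            )
            fit = analysis.fit_diffusion(series, metric=metric)
            report["metrics"][metric] = {
                "drel_plateau": float(np.mean(curve.metric(metric)[-tail:])),
                "drel_max": summary.max_value,
                "argmax_iteration": summary.argmax_iteration,
                "drel_min": summary.min_value,
                "argmin_iteration": summary.argmin_iteration,
                "return_iteration": summary.return_iteration,
                "msd_slope": fit.slope,
                "msd_fit_r2": fit.r_squared,
            }

        if config.n_tracks > 0:
            stage = "tracks"
            tracks = sample_tracks(
                surface, start, config.n_tracks, config.n_iterations, seed=config.seed
            )
            written.append(io.write_tracks_csv(tracks, out / "tracks.csv"))
            report["tracks"] = {"n_tracks": config.n_tracks, "seed": config.seed}

        stage = "report"
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(report_path)
        io.write_manifest(
            out,
            written,
            extra={"config": {k: str(v) for k, v in vars(config).items()}},
        )
        marker.unlink()
        return report
    except Exception as exc:
        if isinstance(exc, (StageError, InvalidSpecError)):
            raise
        raise StageError(stage, str(exc)) from exc
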