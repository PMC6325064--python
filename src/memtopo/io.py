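"""File formats: surfaces, height maps, projections, tables, manifests.

All numeric series are plain CSV; height maps are single-channel TIFF or CSV
grids (one integer height per pixel, row-major, origin top-left); probability
projections are single-channel float TIFF.  Surfaces serialize to a small
versioned text format that stores the volume shape, builder metadata and the
sorted node list — adjacency is always recomputed, never stored.
"""

from __future__ import annotations

import ast
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidSpecError
from .surfaces import SurfaceGraph
from .walk import ProbabilityField, TrackSet

__all__ = [
    "save_surface",
    "load_surface",
    "read_height_map",
    "write_height_map",
    "zproject",
    "write_projection_tiff",
    "write_probability_csv",
    "write_tracks_csv",
    "parse_config",
    "file_checksum",
    "write_manifest",
]

SURFACE_FORMAT = "memtopo-surface v1"


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def _json_safe(obj):
    if isinstance(obj, Mapping):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_surface(surface: SurfaceGraph, path) -> Path:
    """Write the versioned text serialization of a surface."""
    path = Path(path)
    header = [
        f"# {SURFACE_FORMAT}",
        f"# volume_shape: {','.join(str(s) for s in surface.volume_shape)}",
        f"# metadata: {json.dumps(_json_safe(surface.metadata))}",
        "x,y,z",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, surface.nodes, fmt="%d", delimiter=",")
    return path


def load_surface(path) -> SurfaceGraph:
    path = Path(path)
    volume_shape = None
    metadata = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
                body = line[1:].strip()
                if body.startswith("volume_shape:"):
                    volume_shape = tuple(
                        int(v) for v in body.split(":", 1)[1].split(",")
                    )
                elif body.startswith("metadata:"):
                    metadata = json.loads(body.split(":", 1)[1])
                elif body != SURFACE_FORMAT:
                    raise InvalidSpecError(f"unrecognized surface file header: {body!r}")
            else:
                break
    nodes = np.loadtxt(path, dtype=np.int64, delimiter=",", skiprows=n_header + 1, ndmin=2)
    return SurfaceGraph(nodes, volume_shape=volume_shape, metadata=metadata)


# ---------------------------------------------------------------------------
# height maps
# ---------------------------------------------------------------------------


def read_height_map(path) -> np.ndarray:
    """Read a height map from CSV or single-channel TIFF (``heights[y, x]``)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path))
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.ndim != 2:
        raise InvalidSpecError(f"height map in {path} is not a single-channel 2D image")
    if not np.allclose(arr, np.round(arr)):
        raise InvalidSpecError(f"height map in {path} contains non-integer heights")
    return np.round(arr).astype(np.int64)


def write_height_map(heights: np.ndarray, path) -> Path:
    path = Path(path)
    heights = np.asarray(heights)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, heights.astype(np.int32))
    else:
        np.savetxt(path, heights, fmt="%d", delimiter=",")
    return path


# ---------------------------------------------------------------------------
# projections and tables
# ---------------------------------------------------------------------------


def zproject(
    field: ProbabilityField, mode: str = "sum", scale: str = "linear"
) -> np.ndarray:
    """Summed Z-projection of a probability field as a 2D image (``img[y, x]``).

    The unscaled sum image conserves total mass.  ``scale`` transforms are
    display-only copies: ``log`` is ``log10(mass + eps)`` with ``eps`` one
    tenth of the smallest positive mass, ``sqrt`` the square root of the raw
    values.  Vertical structures (pillar sides, ridge walls) collapse onto
    single pixels and can look like artefactual accumulations — the very
    misreading the projection is meant to illustrate.
    """
    if mode != "sum":
        raise InvalidSpecError(f"unsupported projection mode {mode!r}")
    nx, ny, _ = field.surface.volume_shape
    img = np.zeros((ny, nx))
    nodes = field.surface.nodes
    np.add.at(img, (nodes[:, 1], nodes[:, 0]), field.mass)
    if scale == "linear":
        return img
    if scale == "sqrt":
        return np.sqrt(img)
    if scale == "log":
        positive = field.mass[field.mass > 0]
        eps = positive.min() / 10.0 if positive.size else 1e-300
        return np.log10(img + eps)
    raise InvalidSpecError(f"unknown scale {scale!r}")


def write_projection_tiff(image: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def write_probability_csv(field: ProbabilityField, path) -> Path:
    """Sparse per-node table: x, y, z, mass (zero-mass nodes omitted)."""
    path = Path(path)
    field.to_frame(drop_zero=True).to_csv(path, index=False)
    return path


def write_tracks_csv(tracks: TrackSet, path) -> Path:
    path = Path(path)
    tracks.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------


def parse_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Values are evaluated as Python literals where possible (ints, floats,
    tuples, booleans); everything else stays a string.  Blank lines and
    ``#`` comments are ignored.
    """
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidSpecError(f"bad config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = ast.literal_eval(value)
        except (ValueError, SyntaxError):
            out[key] = value
    return out


def file_checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(out_dir, files: Sequence[Path], extra: Mapping | None = None) -> Path:
    """Record every output file with its checksum; deterministic runs reproduce it."""
    out_dir = Path(out_dir)
    entries = {
        str(Path(f).relative_to(out_dir)): file_checksum(f) for f in sorted(map(Path, files))
    }
    manifest = {"files": entries, **_json_safe(dict(extra or {}))}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
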