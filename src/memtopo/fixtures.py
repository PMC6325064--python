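"""Named, reproducible study geometries and their start positions.

Every fixture is built bit-exactly from its name plus parameters (plus a seed
where stochastic).  Each returns the surface together with named start-node
presets — e.g. "midway between two ridges", "centre of a ridge wall", "crown
of the cell" — because the apparent diffusion measured with planar metrics
depends on where the simulation is launched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import CatalogError, InvalidSpecError
from . import surfaces
from .surfaces import SurfaceGraph

__all__ = [
    "Fixture",
    "generate_fixture",
    "list_fixtures",
    "synthetic_cell_height_map",
    "CATALOG",
]


@dataclass
class Fixture:
    name: str
    surface: SurfaceGraph
    starts: dict[str, tuple[int, int, int]]
    params: dict = field(default_factory=dict)

    @property
    def default_start(self) -> tuple[int, int, int]:
        return self.starts["default"]


def _merge(defaults: dict, overrides: dict) -> dict:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise InvalidSpecError(f"unknown fixture overrides: {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides)
    return out


# -- flat ------------------------------------------------------------------


def _flat(**overrides) -> Fixture:
    p = _merge({"width": 1024, "height": 1024, "z": 0}, overrides)
    surf = surfaces.build_flat(p["width"], p["height"], p["z"])
    center = (p["width"] // 2, p["height"] // 2, p["z"])
    return Fixture("flat", surf, {"default": center, "center": center}, p)


# -- folded parallel ridges ------------------------------------------------


def _ridge_start_presets(surf: SurfaceGraph) -> dict[str, tuple[int, int, int]]:
    m = surf.metadata
    w, s, phase, base, h = (
        m["ridge_width"], m["spacing"], m["phase"], m["base"], m["ridge_height"],
    )
    period = w + s
    nx, ny = m["extent"]
    yc = ny // 2
    # the gap whose centre is nearest the middle column
    gap_start = phase - s
    gap_start += period * round((nx // 2 - gap_start) / period)
    gap_mid = gap_start + (s - 1) // 2
    ridge_start = gap_start + s  # first column of the ridge right of that gap
    presets = {
        "default": (gap_mid, yc, base),
        "between_ridges": (gap_mid, yc, base),
    }
    if h > 0:
        presets["wall_center"] = (ridge_start, yc, base + h // 2)
        presets["ridge_top"] = (ridge_start + w // 2, yc, base + h)
    if m["orientation"] == "x":
        presets = {k: (y, x, z) for k, (x, y, z) in presets.items()}
    return presets


def _ridges_folded(**overrides) -> Fixture:
    p = _merge(
        {
            "extent": (275, 637),
            "ridge_height": 4,
            "ridge_width": 4,
            "spacing": 2,
            "orientation": "y",
            "phase": None,
            "base": 0,
        },
        overrides,
    )
    surf = surfaces.build_ridges(
        p["extent"], p["ridge_height"], p["ridge_width"], p["spacing"],
        orientation=p["orientation"], phase=p["phase"], base=p["base"],
    )
    return Fixture("ridges_folded", surf, _ridge_start_presets(surf), p)


# -- slot / notch / control ridge field ------------------------------------


def _ridges_defect(variant: str, **overrides) -> Fixture:
    p = _merge(
        {
            "extent": (1023, 1023),
            "ridge_height": 7,
            "ridge_width": 3,
            "spacing": 9,
            "volume_z": 9,
            "notch_depth": 6,  # cut to one node above the base: the deepest non-through notch
        },
        overrides,
    )
    extent = p["extent"]
    surf = surfaces.build_ridges(
        extent, p["ridge_height"], p["ridge_width"], p["spacing"],
        orientation="y",
        volume_shape=(extent[0], extent[1], p["volume_z"]),
    )
    presets = _ridge_start_presets(surf)
    start = presets["between_ridges"]
    # the defect sits in the ridge to the right of the start, at the start row,
    # so the start is midway between the defect and the next ridge
    s = p["spacing"]
    defect_x = start[0] + (s - (s - 1) // 2)  # first column of the next ridge
    defect_pos = (defect_x, start[1])
    if variant == "slot":
        surf = surfaces.insert_defect(surf, "slot", defect_pos)
    elif variant == "notch":
        surf = surfaces.insert_defect(surf, "notch", defect_pos, depth=p["notch_depth"])
    elif variant != "control":
        raise CatalogError(variant)
    # wall/top presets sit on the defect row and may have been cut away
    presets = {"default": start, "between_ridges": start}
    return Fixture(f"ridges_{variant}", surf, presets, {**p, "defect_pos": defect_pos})


# -- deformed surfaces -----------------------------------------------------


def _pillars(**overrides) -> Fixture:
    p = _merge(
        {
            "extent": (121, 121),
            "base_size": 5,
            "pillar_height": 15,
            "grid_spacing": 12,
            "indent_corners": True,
            "base_z": 0,
        },
        overrides,
    )
    surf = surfaces.build_pillars(
        p["extent"], p["base_size"], p["pillar_height"], p["grid_spacing"],
        p["indent_corners"], p["base_z"],
    )
    hm = surf.height_map
    top = p["base_z"] + p["pillar_height"]
    tops = np.argwhere(hm == top)
    cy, cx = tops[len(tops) // 2]
    ys, xs = np.nonzero(hm == p["base_z"])
    mid = p["extent"][0] // 2, p["extent"][1] // 2
    flat_pick = np.argmin((xs - mid[0]) ** 2 + (ys - mid[1]) ** 2)
    starts = {
        "default": (int(xs[flat_pick]), int(ys[flat_pick]), p["base_z"]),
        "between_pillars": (int(xs[flat_pick]), int(ys[flat_pick]), p["base_z"]),
        "pillar_top": (int(cx), int(cy), top),
    }
    return Fixture("pillars", surf, starts, p)


def _invaginations(**overrides) -> Fixture:
    p = _merge(
        {
            "extent": (121, 121),
            "pit_size": 5,
            "pit_depth": 15,
            "grid_spacing": 12,
            "indent_corners": True,
        },
        overrides,
    )
    surf = surfaces.build_invaginations(
        p["extent"], p["pit_size"], p["pit_depth"], p["grid_spacing"], p["indent_corners"]
    )
    hm = surf.height_map
    ys, xs = np.nonzero(hm == p["pit_depth"])
    mid = p["extent"][0] // 2, p["extent"][1] // 2
    pick = np.argmin((xs - mid[0]) ** 2 + (ys - mid[1]) ** 2)
    pit = np.argwhere(hm == 0)
    py, px = pit[len(pit) // 2]
    starts = {
        "default": (int(xs[pick]), int(ys[pick]), p["pit_depth"]),
        "between_pits": (int(xs[pick]), int(ys[pick]), p["pit_depth"]),
        "pit_bottom": (int(px), int(py), 0),
    }
    return Fixture("invaginations", surf, starts, p)


def _bumps(**overrides) -> Fixture:
    p = _merge(
        {"extent": (97, 97), "bump_height": 2, "bump_size": 2, "spacing": 2, "base": 0},
        overrides,
    )
    surf = surfaces.build_bumps(
        p["extent"], p["bump_height"], p["bump_size"], p["spacing"], p["base"]
    )
    hm = surf.height_map
    ys, xs = np.nonzero(hm == p["base"])
    mid = p["extent"][0] // 2, p["extent"][1] // 2
    pick = np.argmin((xs - mid[0]) ** 2 + (ys - mid[1]) ** 2)
    start = (int(xs[pick]), int(ys[pick]), p["base"])
    return Fixture("bumps", surf, {"default": start}, p)


# -- composite arena -------------------------------------------------------


def _quadrant_arena(**overrides) -> Fixture:
    p = _merge({"quadrant": 128, "base": 6}, overrides)
    q, b = p["quadrant"], p["base"]
    flat_q = surfaces.flat_height_map(q, q, z=b)
    ridges_q = surfaces.ridges_height_map(
        (q, q), ridge_height=4, ridge_width=4, spacing=2, phase=2, base=b
    )
    pillars_q = surfaces.pillars_height_map(
        (q, q), base_size=5, pillar_height=15, grid_spacing=12, base_z=b
    )
    invag_q = surfaces.invaginations_height_map(
        (q, q), pit_size=5, pit_depth=b, grid_spacing=12
    )
    surf = surfaces.build_quadrant_composite(flat_q, ridges_q, pillars_q, invag_q)
    start = (q - 1, q - 1, b)  # the shared corner where the four surfaces meet
    return Fixture("quadrant_arena", surf, {"default": start, "center": start}, p)


# -- synthetic cell --------------------------------------------------------


def synthetic_cell_height_map(
    shape: tuple[int, int] = (256, 256),
    n_crowns: int = 3,
    amplitude: float = 60.0,
    sigma: float = 40.0,
    ridge_amplitude: float = 5.0,
    ridge_period: float = 24.0,
    n_bumps: int = 200,
    bump_amplitude: float = 3.0,
    bump_sigma: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """A cell-like height map: smooth crowns with ridges and small protrusions.

    Emulates the gross features reported for live epithelial cells imaged by
    hopping-probe ion-conductance microscopy — domed cell bodies tens of nodes
    high, superimposed fold-like undulations and microvillus-scale bumps.
    Deterministic for a given seed; the result is quantized to integer node
    heights.
    """
    rng = np.random.default_rng(seed)
    ny, nx = int(shape[0]), int(shape[1])
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    h = np.zeros((ny, nx))
    for _ in range(n_crowns):
        cx = rng.uniform(0.2 * nx, 0.8 * nx)
        cy = rng.uniform(0.2 * ny, 0.8 * ny)
        amp = amplitude * rng.uniform(0.7, 1.0)
        sig = sigma * rng.uniform(0.75, 1.25)
        h += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig * sig))
    # fold-like undulations, scaled by the local cell body height
    theta = rng.uniform(0.0, np.pi)
    carrier = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / ridge_period)
    body = h / (h.max() + 1e-12)
    h += ridge_amplitude * (0.5 + 0.5 * carrier) * body
    # microvillus-scale bumps
    if n_bumps > 0:
        bx = rng.uniform(0, nx, size=n_bumps)
        by = rng.uniform(0, ny, size=n_bumps)
        bamp = bump_amplitude * rng.uniform(0.5, 1.0, size=n_bumps)
        for x0, y0, a in zip(bx, by, bamp):
            h += a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * bump_sigma**2))
    return np.clip(np.rint(h), 0, None).astype(np.int64)


def _synthetic_cell(**overrides) -> Fixture:
    p = _merge(
        {
            "shape": (256, 256),
            "n_crowns": 3,
            "amplitude": 60.0,
            "sigma": 40.0,
            "ridge_amplitude": 5.0,
            "ridge_period": 24.0,
            "n_bumps": 200,
            "bump_amplitude": 3.0,
            "bump_sigma": 2.0,
            "seed": 0,
        },
        overrides,
    )
    hm = synthetic_cell_height_map(**p)
    surf = surfaces.build_from_height_map(
        hm, metadata={"builder": "synthetic_cell", **{k: p[k] for k in ("seed", "n_crowns")}}
    )
    iy, ix = np.unravel_index(int(np.argmax(hm)), hm.shape)
    crown = (int(ix), int(iy), int(hm[iy, ix]))
    return Fixture("synthetic_cell", surf, {"default": crown, "crown": crown}, p)


CATALOG: dict[str, Callable[..., Fixture]] = {
    "flat": _flat,
    "ridges_folded": _ridges_folded,
    "ridges_control": lambda **o: _ridges_defect("control", **o),
    "ridges_slot": lambda **o: _ridges_defect("slot", **o),
    "ridges_notch": lambda **o: _ridges_defect("notch", **o),
    "pillars": _pillars,
    "invaginations": _invaginations,
    "bumps": _bumps,
    "quadrant_arena": _quadrant_arena,
    "synthetic_cell": _synthetic_cell,
}

_DESCRIPTIONS = {
    "flat": "flat horizontal sheet (baseline geometry)",
    "ridges_folded": "folded surface: parallel ridges, height 4, width 4, spacing 2",
    "ridges_control": "ridges height 7, width 3, 12-node period, 1023x1023x9 volume",
    "ridges_slot": "same ridge field with a one-node-wide full-height slot",
    "ridges_notch": "same ridge field with a one-node-wide notch cut from the top",
    "pillars": "corner-indented 5x5 pillars, 15 high, hexagonal 12-node grid",
    "invaginations": "square pits sunk into a raised plane (inverted pillars)",
    "bumps": "dense grid of small square bumps (highly deformed)",
    "quadrant_arena": "flat / ridges / pillars / invaginations meeting at one corner",
    "synthetic_cell": "seeded cell-like height map: crowns + folds + bumps",
}


def generate_fixture(name: str, **overrides) -> Fixture:
    """Build a catalog surface with its start-node presets.

    Overrides replace the named default parameters; unknown names raise
    :class:`CatalogError`.
    """
    try:
        factory = CATALOG[name]
    except KeyError:
        raise CatalogError(f"unknown fixture {name!r}; known: {sorted(CATALOG)}") from None
    return factory(**overrides)


def list_fixtures() -> dict[str, str]:
    return dict(_DESCRIPTIONS)
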