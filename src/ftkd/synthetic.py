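"""Synthetic microscopy-like honeycombs with planted ground truth.

Stands in for en face whole-mount ZO-1 imagery: an ideal interdigitated
lattice honeycomb is scaled so the mean single-edged polygon area matches
the observed ~905.8 µm², double-edged pairs are planted at a configurable
rate (default 9.8%) on mutually non-adjacent columns, and vertex positions
receive i.i.d. Gaussian jitter (applied per shared mesh vertex, so seams
stay seams).  What this emulates — and what it does not (no point-spread
blur, no segmentation errors, no tissue curvature) — is discussed in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Snapshot, TRANSITION
from .geometry import build_lattice, ColumnLattice
from .honeycomb import TJGraph, TJPolygon, extract_honeycomb
from .morphometry import area_scale_for_target, TARGET_SINGLE_AREA

__all__ = ["SynthConfig", "make_noisy_honeycomb", "make_fixture", "StarFixture"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic honeycomb generator."""

    target_single_area: float = TARGET_SINGLE_AREA   # µm²
    double_rate_percent: float = 9.8
    jitter_xy_um: float = 0.0
    jitter_z_um: float = 0.0
    z_offset_exterior: float = 0.0    # µm, additive per class
    z_offset_interior: float = 0.0
    z_offset_single: float = 0.0
    flatten_ratio: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.double_rate_percent <= 100:
            raise ValueError("double_rate_percent must be in [0, 100]")
        if self.jitter_xy_um < 0 or self.jitter_z_um < 0:
            raise ValueError("jitter standard deviations must be >= 0")
        if self.target_single_area <= 0:
            raise ValueError("target_single_area must be positive")


def _ideal_state(lattice: ColumnLattice) -> tuple[np.ndarray, np.ndarray]:
    """The canonical steady barrier state: every column at its class height.

    Height classes 0, 1/3, 2/3 give the generic steady mixture of polygon
    sizes: lowest columns show apical-hexagon polygons, middle columns
    intermediate rings, highest columns maximal rings.
    """
    return np.zeros(lattice.n_columns, dtype=np.int8), lattice.phi.astype(np.int64).copy()


def make_noisy_honeycomb(config: SynthConfig, nx: int = 21, ny: int = 21
                         ) -> tuple[TJGraph, pd.DataFrame]:
    """Generate a microscopy-like honeycomb plus ground-truth labels.

    Double-edged pairs are planted on randomly chosen highest-class columns
    (mutually non-adjacent by construction: columns of equal height class
    are never lateral neighbours).  Raises when the requested rate exceeds
    the one-in-three columns that can host a non-adjacent pair.
    """
    rng = np.random.default_rng(config.seed)
    lattice0 = build_lattice(nx, ny, flatten_ratio=config.flatten_ratio)
    phase, h3 = _ideal_state(lattice0)
    n = lattice0.n_columns
    candidates = np.flatnonzero(lattice0.phi == 2)
    n_plant = int(round(config.double_rate_percent / 100.0 * n))
    if n_plant > len(candidates):
        raise ValueError(
            f"planting rate {config.double_rate_percent}% needs {n_plant} "
            f"non-adjacent host columns but only {len(candidates)} exist "
            "(at most one column in three can host a pair)")
    planted = rng.choice(candidates, size=n_plant, replace=False)
    phase[planted] = TRANSITION
    h3[planted] -= 3

    # calibrate the µm scale on the unscaled mesh, then realize at scale
    snap0 = Snapshot(0.0, phase, h3, lattice0)
    g0 = extract_honeycomb(snap0)
    mean_single = float(np.mean([p.enface_area for p in g0.singles]))
    scale = area_scale_for_target(mean_single, config.target_single_area)
    lattice = build_lattice(nx, ny, flatten_ratio=config.flatten_ratio, scale=scale)
    graph = extract_honeycomb(Snapshot(0.0, phase, h3, lattice))

    if config.jitter_xy_um or config.jitter_z_um:
        offsets: dict[bytes, np.ndarray] = {}
        for p in graph.polygons:
            for key in p.vertex_keys:
                if key not in offsets:
                    offsets[key] = np.array([
                        rng.normal(0.0, config.jitter_xy_um),
                        rng.normal(0.0, config.jitter_xy_um),
                        rng.normal(0.0, config.jitter_z_um),
                    ])
        for p in graph.polygons:
            p.vertices = p.vertices + np.stack([offsets[k] for k in p.vertex_keys])
    class_dz = {"single": config.z_offset_single,
                "exterior": config.z_offset_exterior,
                "interior": config.z_offset_interior}
    for p in graph.polygons:
        dz = class_dz[p.kind]
        if dz:
            p.vertices = p.vertices + np.array([0.0, 0.0, dz])

    truth = pd.DataFrame({
        "column": np.arange(n),
        "planted_double": np.isin(np.arange(n), planted),
        "height_class": lattice.phi,
    })
    return graph, truth


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

@dataclass
class StarFixture:
    """Seven-column star: one centre column with its six lateral neighbours
    inside a small open lattice, centre highest."""

    lattice: ColumnLattice
    columns: list[int]
    center: int
    phase: np.ndarray
    h3: np.ndarray

    def snapshot(self, t: float = 0.0) -> Snapshot:
        return Snapshot(t, self.phase, self.h3, self.lattice)


def _star7() -> StarFixture:
    lattice = build_lattice(5, 5, periodic=False)
    center = 2 * 5 + 2
    ring = [int(lattice.neighbors[center, d]) for d in range(6)]
    phase = np.zeros(lattice.n_columns, dtype=np.int8)
    # centre one full cell above its class height; every other column at its
    # class height -> centre strictly higher than all six neighbours
    h3 = lattice.phi.astype(np.int64).copy()
    h3[center] += 3
    return StarFixture(lattice, [center] + ring, center, phase, h3)


def _column_pair() -> tuple[TJGraph, int]:
    """Smallest periodic lattice with exactly one double-edged pair."""
    lattice = build_lattice(3, 3)
    phase, h3 = _ideal_state(lattice)
    host = int(np.flatnonzero(lattice.phi == 2)[0])
    phase[host] = TRANSITION
    h3[host] -= 3
    return extract_honeycomb(Snapshot(0.0, phase, h3, lattice)), host


def _hexprism(slide: float = 0.5, slid_column: int | None = 4) -> TJGraph:
    """Hexagonal-prism comparison lattice (the non-interdigitated straw man).

    Simple columnar packing: every column's TJ ring is the Voronoi hexagon
    of the triangular column grid, all at one apical plane, seams exactly
    shared.  Sliding one column upward by ``slide`` cell heights moves its
    ring out of the common plane: the en face projection still covers, but
    the seams no longer coincide in 3D — the barrier tears.  Heights are in
    units of the cell height.
    """
    nx = ny = 3
    lattice = build_lattice(nx, ny)
    a1, a2 = lattice.inplane_vectors
    # Voronoi hexagon corners: circumcenters of the six triangles around a
    # site; integer bookkeeping at 3x resolution for exact shared keys
    corner_steps = []
    step_dirs = [(1, 0), (1, 1), (0, 1), (-1, 0), (-1, -1), (0, -1)]
    for k in range(6):
        s1 = step_dirs[k]
        s2 = step_dirs[(k + 1) % 6]
        corner_steps.append((s1[0] + s2[0], s1[1] + s2[1]))
    polys: list[TJPolygon] = []
    for col in range(lattice.n_columns):
        i, j = lattice.col_ij(col)
        z = slide if col == slid_column else 0.0
        zcode = 1 if col == slid_column else 0
        verts, vkeys = [], []
        for (ci, cj) in corner_steps:
            ii, jj = 3 * i + ci, 3 * j + cj
            xy = (ii * a1 + jj * a2) / 3.0
            verts.append([xy[0], xy[1], z])
            vkeys.append(repr(((ii % (3 * nx)), (jj % (3 * ny)), zcode)).encode())
        m = 6
        ekeys = []
        for k in range(m):
            a, b = vkeys[k], vkeys[(k + 1) % m]
            ekeys.append(a + b if a <= b else b + a)
        polys.append(TJPolygon(
            poly_id=col, column=col, kind="single",
            vertices=np.asarray(verts),
            seam_classes=["bTJ"] * m,
            seam_cells=[((col, 0),)] * m,
            edge_keys=ekeys, vertex_keys=vkeys,
            ttj_vertex_flags=[False] * m,
        ))
    return TJGraph(polys, lattice, timestamp=0.0)


def make_fixture(kind: str):
    """Deterministic test scenes.

    ``star7``: seven-column star, centre highest (engine-rule fixture).
    ``column_pair``: 3x3 periodic honeycomb with exactly one nested pair.
    ``hexprism_strawman``: hexagonal-prism lattice with one column slid
    upward, breaking barrier continuity.
    """
    if kind == "star7":
        return _star7()
    if kind == "column_pair":
        return _column_pair()
    if kind == "hexprism_strawman":
        return _hexprism()
    raise ValueError(f"unknown fixture kind {kind!r}")
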