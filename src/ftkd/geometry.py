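"""Flattened tetrakaidecahedron (f-TKD) cell geometry and the interdigitated
column lattice of the granular-layer barrier.

The basic cell is Kelvin's tetrakaidecahedron — the truncated octahedron,
built exactly from the 24 permutations of (0, ±1, ±2) — rotated so that a
body diagonal (a hexagonal-face normal) points along the stacking axis and
then scaled along that axis by a flattening ratio.  Cells tile space on a
BCC lattice; viewed along the stacking axis the cell columns form a
triangular lattice whose columns fall into three height classes offset by
0, 1/3 and 2/3 of the stacking period, so that every column has six lateral
neighbour columns, three whose nearest cell sits a third of a period higher
and three a third lower.  Each cell touches 14 neighbours: two stacked
(apical/basal hexagons), six through tilted hexagons (cells ±1/3 period
away) and six through squares (cells ±2/3 period away).

All topology is computed in exact integer coordinates; the rotation,
flattening and micrometre scaling are applied as a final affine map, so
face/edge coincidence tests are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np

__all__ = [
    "FTKDPolyhedron",
    "ColumnLattice",
    "Ring",
    "make_canonical_tkd",
    "build_lattice",
    "apical_tj_ring",
    "UP_DIRS",
    "DOWN_DIRS",
    "N_DIRS",
]

# The three in-plane lattice steps toward columns whose nearest cell sits a
# third of a period HIGHER, then the three toward columns a third LOWER.
UP_DIRS = ((1, 1), (0, -1), (-1, 0))
DOWN_DIRS = ((-1, -1), (0, 1), (1, 0))
DIRS = UP_DIRS + DOWN_DIRS
N_DIRS = 6

# Cubic lattice basis of the BCC packing (integer coordinates).
A1 = np.array([4, 0, 0])
A2 = np.array([0, 4, 0])
A3 = np.array([2, 2, 2])  # stacking step: one period along the body diagonal

# Rotation taking the body diagonal (1,1,1) to the z axis (rows are the
# orthonormal image axes).
_SQ2, _SQ6, _SQ3 = np.sqrt(2.0), np.sqrt(6.0), np.sqrt(3.0)
ROT = np.array(
    [
        [1 / _SQ2, -1 / _SQ2, 0],
        [1 / _SQ6, 1 / _SQ6, -2 / _SQ6],
        [1 / _SQ3, 1 / _SQ3, 1 / _SQ3],
    ]
)
PERIOD = 2 * _SQ3  # stacking period |A3| along the axis, in lattice units


def realize(points_int: np.ndarray, flatten_ratio: float, scale: float = 1.0) -> np.ndarray:
    """Map integer lattice coordinates to physical coordinates.

    Rotates the body diagonal onto z, compresses z by ``flatten_ratio`` and
    applies the isotropic in-plane ``scale`` (micrometres per lattice unit).
    """
    p = np.asarray(points_int, dtype=float) @ ROT.T
    p[..., 2] *= flatten_ratio
    return p * scale


# ---------------------------------------------------------------------------
# canonical truncated octahedron
# ---------------------------------------------------------------------------

def _canonical_vertices() -> np.ndarray:
    verts = set()
    for a in (1, -1):
        for b in (2, -2):
            verts.update(permutations((0, a, b)))
    out = np.array(sorted(verts), dtype=np.int64)
    assert out.shape == (24, 3)
    return out


def _order_cycle(vids: Sequence[int], verts: np.ndarray, normal: np.ndarray) -> list[int]:
    """Order face vertices counter-clockwise around the outward normal."""
    pts = verts[list(vids)].astype(float)
    c = pts.mean(axis=0)
    n = normal / np.linalg.norm(normal)
    u = pts[0] - c
    u -= n * (u @ n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    ang = np.arctan2((pts - c) @ v, (pts - c) @ u)
    return [vids[k] for k in np.argsort(ang)]


@dataclass(frozen=True)
class Face:
    """One face of the cell with its tessellation bookkeeping.

    ``partner_center`` is the integer offset to the centre of the unique
    neighbouring cell sharing this face; ``partner_dij``/``partner_dthirds``
    locate that neighbour as (column step, height change in thirds of a
    period).  ``partner_dij`` is ``None`` for the stacked (apical/basal)
    neighbours, which live in the same column.
    """

    indices: tuple[int, ...]
    kind: str          # "hexagon" | "square"
    orientation: str   # "apical" | "basal" | "lateral-upper" | "lateral-lower"
    normal_int: tuple[int, int, int]
    partner_center: tuple[int, int, int]
    partner_dij: tuple[int, int] | None
    partner_dthirds: int


def _canonical_faces(verts: np.ndarray) -> list[Face]:
    ones = np.ones(3)
    faces: list[Face] = []
    # mapping from face normal to the lateral direction it serves
    hex_up = {(1, 1, -1): (1, 1), (1, -1, 1): (0, -1), (-1, 1, 1): (-1, 0)}
    hex_dn = {(1, -1, -1): (1, 0), (-1, 1, -1): (0, 1), (-1, -1, 1): (-1, -1)}
    sq_up = {(1, 0, 0): (1, 0), (0, 1, 0): (0, 1), (0, 0, 1): (-1, -1)}
    sq_dn = {(-1, 0, 0): (-1, 0), (0, -1, 0): (0, -1), (0, 0, -1): (1, 1)}

    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                s = np.array([sx, sy, sz])
                vids = [i for i, v in enumerate(verts) if v @ s == 3]
                cyc = tuple(_order_cycle(vids, verts, s.astype(float)))
                axis = int(s @ ones)  # +3 apical, +1 upper, -1 lower, -3 basal
                if axis == 3:
                    orient, dij, dth = "apical", None, 3
                elif axis == -3:
                    orient, dij, dth = "basal", None, -3
                elif axis == 1:
                    orient, dij, dth = "lateral-upper", hex_up[(sx, sy, sz)], 1
                else:
                    orient, dij, dth = "lateral-lower", hex_dn[(sx, sy, sz)], -1
                faces.append(
                    Face(cyc, "hexagon", orient, (sx, sy, sz),
                         tuple(2 * s), dij, dth)
                )
    for ax in range(3):
        for sgn in (1, -1):
            e = np.zeros(3, dtype=np.int64)
            e[ax] = sgn
            vids = [i for i, v in enumerate(verts) if v[ax] == 2 * sgn]
            cyc = tuple(_order_cycle(vids, verts, e.astype(float)))
            if sgn > 0:
                orient = "lateral-upper"
                dij, dth = sq_up[tuple(e)], 2
            else:
                orient = "lateral-lower"
                dij, dth = sq_dn[tuple(e)], -2
            faces.append(Face(cyc, "square", orient, tuple(e), tuple(4 * e), dij, dth))
    return faces


_CANON_VERTS = _canonical_vertices()
_CANON_FACES = _canonical_faces(_CANON_VERTS)


def _canonical_edges() -> list[tuple[int, int]]:
    edges = set()
    for f in _CANON_FACES:
        n = len(f.indices)
        for k in range(n):
            a, b = f.indices[k], f.indices[(k + 1) % n]
            edges.add((min(a, b), max(a, b)))
    assert len(edges) == 36
    return sorted(edges)


_CANON_EDGES = _canonical_edges()

# sorted edge -> ids of the two faces containing it
_EDGE_FACES: dict[tuple[int, int], tuple[int, int]] = {}
for _fi, _f in enumerate(_CANON_FACES):
    _n = len(_f.indices)
    for _k in range(_n):
        _e = tuple(sorted((_f.indices[_k], _f.indices[(_k + 1) % _n])))
        _EDGE_FACES.setdefault(_e, ())
        _EDGE_FACES[_e] = _EDGE_FACES[_e] + (_fi,)

# vertex -> ids of the three faces meeting there
_VERT_FACES: dict[int, tuple[int, ...]] = {i: () for i in range(24)}
for _fi, _f in enumerate(_CANON_FACES):
    for _vi in _f.indices:
        _VERT_FACES[_vi] = _VERT_FACES[_vi] + (_fi,)

APICAL_FACE_ID = next(i for i, f in enumerate(_CANON_FACES) if f.orientation == "apical")
# direction index (0..5) -> id of the upper contact face serving it
_UPPER_FACE_OF_DIR: dict[int, int] = {}
for _fi, _f in enumerate(_CANON_FACES):
    if _f.partner_dij is not None and _f.partner_dthirds in (1, 2):
        _UPPER_FACE_OF_DIR[DIRS.index(_f.partner_dij)] = _fi
assert len(_UPPER_FACE_OF_DIR) == 6


@dataclass
class FTKDPolyhedron:
    """A single flattened Kelvin tetrakaidecahedron.

    24 vertices, 36 edges, 14 faces (8 hexagons, 6 squares).  ``vertices``
    are the realized (rotated/flattened/scaled) coordinates; the exact
    integer coordinates are kept alongside for topological queries.
    """

    vertices: np.ndarray
    vertices_int: np.ndarray
    edges: list[tuple[int, int]]
    faces: list[Face]
    flatten_ratio: float
    scale: float = 1.0
    center_int: tuple[int, int, int] = (0, 0, 0)

    @property
    def n_hexagons(self) -> int:
        return sum(1 for f in self.faces if f.kind == "hexagon")

    @property
    def n_squares(self) -> int:
        return sum(1 for f in self.faces if f.kind == "square")

    def face_vertices(self, face: Face) -> np.ndarray:
        return self.vertices[list(face.indices)]


def make_canonical_tkd(flatten_ratio: float = 0.25, scale: float = 1.0,
                       center_int: Sequence[int] = (0, 0, 0)) -> FTKDPolyhedron:
    """Construct the (flattened) truncated octahedron.

    Parameters
    ----------
    flatten_ratio:
        Compression of the stacking axis, in (0, 1].  1 gives Kelvin's
        canonical cell; the granular-layer default elsewhere in the package
        is 0.25 (visibly flattened).
    scale:
        Micrometres per lattice unit (isotropic, applied after flattening).
    """
    if not flatten_ratio > 0:
        raise ValueError(f"flatten_ratio must be positive, got {flatten_ratio}")
    off = np.asarray(center_int, dtype=np.int64)
    vint = _CANON_VERTS + off
    return FTKDPolyhedron(
        vertices=realize(vint, flatten_ratio, scale),
        vertices_int=vint,
        edges=list(_CANON_EDGES),
        faces=list(_CANON_FACES),
        flatten_ratio=flatten_ratio,
        scale=scale,
        center_int=tuple(int(x) for x in off),
    )


# ---------------------------------------------------------------------------
# column lattice
# ---------------------------------------------------------------------------

@dataclass
class ColumnLattice:
    """Triangular grid of f-TKD cell columns (the granular-layer stack).

    Columns are indexed ``col = i * ny + j``.  ``phi[col]`` in {0,1,2} is the
    height class: the cells of a column sit at heights ``(phi + 3k)/3``
    stacking periods.  ``neighbors[col, d]`` follows ``UP_DIRS + DOWN_DIRS``
    (first three neighbours a third of a period up, last three down); -1
    marks a missing neighbour on non-periodic lattices.
    """

    nx: int
    ny: int
    n_layers: int
    flatten_ratio: float
    periodic: bool = True
    scale: float = 1.0
    phi: np.ndarray = field(init=False)
    neighbors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.periodic:
            if self.nx < 3 or self.ny < 3:
                raise ValueError("periodic lattice needs nx, ny >= 3")
            if self.nx % 3 or self.ny % 3:
                # the wrap must preserve the mod-3 height-class pattern of the
                # interdigitated stacking; other sizes cannot tile the torus
                raise ValueError(
                    "periodic interdigitated lattice needs nx and ny divisible "
                    f"by 3, got {self.nx}x{self.ny}"
                )
        if self.n_layers < 2:
            raise ValueError("need n_layers >= 2")
        ii, jj = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        self.phi = ((2 * (ii + jj)) % 3).ravel().astype(np.int64)
        nbr = np.full((self.nx * self.ny, 6), -1, dtype=np.int64)
        for d, (di, dj) in enumerate(DIRS):
            ni, nj = ii + di, jj + dj
            if self.periodic:
                nbr[:, d] = (ni % self.nx * self.ny + nj % self.ny).ravel()
            else:
                ok = (ni >= 0) & (ni < self.nx) & (nj >= 0) & (nj < self.ny)
                flat = (np.clip(ni, 0, self.nx - 1) * self.ny
                        + np.clip(nj, 0, self.ny - 1)).ravel()
                flat[~ok.ravel()] = -1
                nbr[:, d] = flat
        self.neighbors = nbr

    # -- index helpers ----------------------------------------------------
    @property
    def n_columns(self) -> int:
        return self.nx * self.ny

    def col_ij(self, col: int) -> tuple[int, int]:
        return divmod(int(col), self.ny)

    def cell_center_int(self, col: int, thirds: int) -> np.ndarray:
        """Integer centre of the cell of ``col`` whose top sits ``thirds/3``
        periods up (``thirds`` must be ≡ phi (mod 3))."""
        i, j = self.col_ij(col)
        if (thirds - self.phi[col]) % 3:
            raise ValueError("height not attainable in this column")
        m = (thirds - 2 * (i + j)) // 3
        return i * A1 + j * A2 + m * A3

    def column_xy(self, col: int) -> np.ndarray:
        i, j = self.col_ij(col)
        c = i * A1 + j * A2
        return realize(c, self.flatten_ratio, self.scale)[:2]

    @property
    def inplane_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        a1 = realize(A1, self.flatten_ratio, self.scale)[:2]
        a2 = realize(A2, self.flatten_ratio, self.scale)[:2]
        return a1, a2

    @property
    def domain_area(self) -> float:
        """En face area of the periodic domain (physical units)."""
        return self.nx * self.ny * self.column_footprint

    @property
    def column_footprint(self) -> float:
        a1, a2 = self.inplane_vectors
        return abs(float(a1[0] * a2[1] - a1[1] * a2[0]))

    def cell(self, col: int, thirds: int) -> FTKDPolyhedron:
        return make_canonical_tkd(self.flatten_ratio, self.scale,
                                  self.cell_center_int(col, thirds))

    def cells(self):
        """All cells of the finite realization (top layer first)."""
        for col in range(self.n_columns):
            for k in range(self.n_layers):
                yield col, int(self.phi[col]) - 3 * k

    # -- torus wrapping ----------------------------------------------------
    def wrap_int(self, v: np.ndarray) -> np.ndarray:
        """Reduce integer coordinates modulo the torus identifications.

        Exact integer arithmetic: the in-plane fractional column coordinates
        of ``v`` are 4a = x - z, 4b = y - z.
        """
        if not self.periodic:
            return np.asarray(v, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        t1 = self.nx * A1 - (2 * self.nx // 3) * A3
        t2 = self.ny * A2 - (2 * self.ny // 3) * A3
        a4 = v[..., 0] - v[..., 2]
        b4 = v[..., 1] - v[..., 2]
        p = np.floor_divide(a4, 4 * self.nx)
        q = np.floor_divide(b4, 4 * self.ny)
        return v - np.multiply.outer(p, t1) - np.multiply.outer(q, t2)


def build_lattice(n_cols_x: int, n_cols_y: int, n_layers: int = 3,
                  flatten_ratio: float = 0.25, periodic: bool = True,
                  scale: float = 1.0) -> ColumnLattice:
    """Build the interdigitated f-TKD column lattice.

    Periodic lattices require column counts divisible by 3 so the wrap
    preserves the three height classes of the BCC stacking.
    """
    return ColumnLattice(n_cols_x, n_cols_y, n_layers, flatten_ratio,
                         periodic, scale)


# ---------------------------------------------------------------------------
# apical TJ rings
# ---------------------------------------------------------------------------

@dataclass
class Ring:
    """A closed cycle of cell edges carrying tight junctions.

    ``vertices`` are ordered realized coordinates (closed implicitly);
    ``vertices_int`` the matching integer coordinates; ``edge_faces[k]``
    gives, for the edge from vertex k to k+1, the (inside, outside) face ids
    on the owning cell — the outside face identifies the third cell sharing
    the seam.
    """

    vertices: np.ndarray
    vertices_int: np.ndarray
    edge_faces: list[tuple[int, int]]
    column: int
    top_thirds: int

    @property
    def n_edges(self) -> int:
        return len(self.edge_faces)


@lru_cache(maxsize=None)
def _ring_template(free_mask: int) -> tuple[tuple[int, ...], tuple[tuple[int, int], ...]]:
    """Boundary cycle of {apical hexagon} ∪ {free upper contact faces}.

    ``free_mask`` has bit d set when the upper face toward direction d is not
    covered by a neighbouring barrier cell.  Returns (vertex cycle, per-edge
    (inside face, outside face)) in canonical coordinates, oriented CCW en
    face.
    """
    in_faces = {APICAL_FACE_ID}
    for d in range(6):
        if free_mask >> d & 1:
            in_faces.add(_UPPER_FACE_OF_DIR[d])
    # boundary edges: in exactly one member face
    count: dict[tuple[int, int], int] = {}
    for fi in in_faces:
        f = _CANON_FACES[fi]
        n = len(f.indices)
        for k in range(n):
            e = tuple(sorted((f.indices[k], f.indices[(k + 1) % n])))
            count[e] = count.get(e, 0) + 1
    boundary = [e for e, c in count.items() if c == 1]
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    assert all(len(v) == 2 for v in adj.values()), "ring is not a simple cycle"
    start = boundary[0][0]
    cycle = [start, adj[start][0]]
    while cycle[-1] != start:
        nxt = [v for v in adj[cycle[-1]] if v != cycle[-2]]
        cycle.append(nxt[0])
    cycle = cycle[:-1]
    # orient CCW in the en face projection
    pts = realize(_CANON_VERTS[cycle], 1.0)
    area2 = 0.0
    for k in range(len(cycle)):
        x1, y1 = pts[k][:2]
        x2, y2 = pts[(k + 1) % len(cycle)][:2]
        area2 += x1 * y2 - x2 * y1
    if area2 < 0:
        cycle = cycle[::-1]
    edge_faces = []
    for k in range(len(cycle)):
        e = tuple(sorted((cycle[k], cycle[(k + 1) % len(cycle)])))
        f1, f2 = _EDGE_FACES[e]
        if f1 in in_faces and f2 not in in_faces:
            edge_faces.append((f1, f2))
        elif f2 in in_faces and f1 not in in_faces:
            edge_faces.append((f2, f1))
        else:  # pragma: no cover - boundary edges always straddle the union
            raise AssertionError("boundary edge inside union")
    return tuple(cycle), tuple(edge_faces)


def apical_tj_ring(lattice: ColumnLattice, column: int, top_thirds: int,
                   covered: Sequence[bool]) -> Ring:
    """The apical tight-junction ring of the top barrier cell of ``column``.

    ``covered[d]`` says whether the upper contact face toward lateral
    direction d (order ``UP_DIRS + DOWN_DIRS``) is held by a neighbouring
    TJ-bearing (SG2) cell.  Junctions sit at the apical edges of the covered
    contacts; toward turned-over neighbours the ring drops to the widest
    extent of the cell.  With all six neighbours lower the ring is the
    maximal cross-section circuit; with all six higher it hugs the apical
    hexagon.
    """
    if len(covered) != 6:
        raise ValueError("covered must have six entries")
    mask = 0
    for d in range(6):
        if not covered[d]:
            mask |= 1 << d
    cycle, edge_faces = _ring_template(mask)
    center = lattice.cell_center_int(column, top_thirds)
    vint = _CANON_VERTS[list(cycle)] + center
    return Ring(
        vertices=realize(vint, lattice.flatten_ratio, lattice.scale),
        vertices_int=vint,
        edge_faces=list(edge_faces),
        column=column,
        top_thirds=top_thirds,
    )


# face id -> (direction index or -1 for same column, height change in thirds)
_FACE_PARTNER_DIR: list[tuple[int, int]] = [
    (-1 if f.partner_dij is None else DIRS.index(f.partner_dij), f.partner_dthirds)
    for f in _CANON_FACES
]


def face_partner(lattice: ColumnLattice, column: int, cell_thirds: int,
                 face_id: int) -> tuple[int, int]:
    """(column, height-thirds) of the cell across ``face_id`` from
    (column, cell_thirds)."""
    d, dth = _FACE_PARTNER_DIR[face_id]
    if d < 0:
        return column, cell_thirds + dth
    return int(lattice.neighbors[column, d]), cell_thirds + dth
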