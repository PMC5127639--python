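"""Extraction and auditing of the en face tight-junction honeycomb.

From a simulation snapshot the module builds the TJ graph: one closed
apical ring per column (the single-edged polygon), plus, for columns in the
double-edged state, the nested pair — the exiting cell's pre-existing
exterior ring and the incoming cell's interior ring, which is its apical
hexagon.  Seams are classified by the junction production rules: a seam
shared by two barrier cells (and touching an already-differentiated cell)
is bicellular (bTJ); a seam shared by three barrier cells is tricellular
(tTJ).  Tricellular points at the vertices of single-edged polygons are
recorded but flagged not-displayed.

The displayed polygons (singles + exteriors) form an exact seam-shared
tiling of the periodic plane; ``barrier_continuity`` audits that property,
which is the model's statement of barrier homeostasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .engine import Snapshot, TRANSITION
from .geometry import (ColumnLattice, Ring, apical_tj_ring, face_partner,
                       _VERT_FACES)

__all__ = [
    "TJPolygon", "TJGraph",
    "extract_honeycomb", "classify_double_edged", "barrier_continuity",
    "neighbors_of_polygon",
]

BTJ, TTJ = "bTJ", "tTJ"


@dataclass
class TJPolygon:
    """One closed TJ polygon (ring) of the honeycomb."""

    poly_id: int
    column: int
    kind: str                     # "single" | "exterior" | "interior"
    vertices: np.ndarray          # (m, 3) realized coords, ordered, closed implicitly
    seam_classes: list[str]       # per edge (vertex k -> k+1)
    seam_cells: list[tuple]       # per edge: barrier cells (column, thirds) sharing it
    edge_keys: list[bytes]        # torus-wrapped integer edge identities
    vertex_keys: list[bytes]
    pair_id: int | None = None    # exterior <-> interior partner
    displayed: bool = True        # interiors are displayed; single-polygon
    ttj_vertex_flags: list[bool] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.seam_classes)

    def shapely(self) -> Polygon:
        return Polygon(self.vertices[:, :2])

    @property
    def enface_area(self) -> float:
        return self.shapely().area

    @property
    def mean_z(self) -> float:
        return float(self.vertices[:, 2].mean())


@dataclass
class TJGraph:
    """The honeycomb at one time point."""

    polygons: list[TJPolygon]
    lattice: ColumnLattice
    timestamp: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self._by_column: dict[int, list[TJPolygon]] = {}
        for p in self.polygons:
            self._by_column.setdefault(p.column, []).append(p)
        self._edge_index: dict[bytes, list[int]] = {}
        self._vertex_index: dict[bytes, list[int]] = {}
        for p in self.polygons:
            if p.kind == "interior":
                continue  # interiors are nested below the tiling
            for k in p.edge_keys:
                self._edge_index.setdefault(k, []).append(p.poly_id)
            for k in p.vertex_keys:
                lst = self._vertex_index.setdefault(k, [])
                if p.poly_id not in lst:
                    lst.append(p.poly_id)

    def polygon(self, poly_id: int) -> TJPolygon:
        try:
            return self.polygons[poly_id]
        except IndexError:
            raise KeyError(f"unknown polygon id {poly_id}") from None

    def column_polygons(self, column: int) -> list[TJPolygon]:
        return self._by_column.get(column, [])

    @property
    def singles(self) -> list[TJPolygon]:
        return [p for p in self.polygons if p.kind == "single"]

    @property
    def pairs(self) -> list[tuple[TJPolygon, TJPolygon]]:
        ext = {p.pair_id: p for p in self.polygons if p.kind == "exterior"}
        return [(ext[p.pair_id], p) for p in self.polygons
                if p.kind == "interior" and p.pair_id in ext]

    @property
    def double_edged_fraction(self) -> float:
        n_pairs = sum(1 for p in self.polygons if p.kind == "interior")
        n_polys = len(self.singles) + n_pairs  # each pair counted once
        return n_pairs / n_polys if n_polys else 0.0


def _ring_keys(lattice: ColumnLattice, vints: np.ndarray) -> tuple[list[bytes], list[bytes]]:
    """Torus-wrapped identities for a ring's vertices and edges."""
    w = lattice.wrap_int(vints).astype(np.int64)
    vkeys = [row.tobytes() for row in w]
    m = len(vkeys)
    ekeys = []
    for k in range(m):
        a, b = vkeys[k], vkeys[(k + 1) % m]
        ekeys.append(a + b if a <= b else b + a)
    return vkeys, ekeys


def _sg2_sets(snapshot: Snapshot) -> list[set[int]]:
    """Per column, the set of barrier-cell heights (thirds)."""
    out = []
    for col in range(len(snapshot.phase)):
        out.append(set(snapshot.sg2_heights(col)))
    return out


def _ring_to_polygon(lattice: ColumnLattice, ring: Ring, sg2: list[set[int]],
                     poly_id: int, kind: str, pair_id: int | None,
                     cell_thirds: int) -> TJPolygon:
    """Classify a ring's seams and build the polygon record.

    ``cell_thirds`` is the height of the ring's owning cell; each seam's
    sharing set is the owner plus the partners across the two faces meeting
    at that edge, filtered to currently TJ-bearing cells.
    """
    col = ring.column
    classes, cells = [], []
    for f_in, f_out in ring.edge_faces:
        sharing = [(col, cell_thirds)]
        for fid in (f_in, f_out):
            pcol, pth = face_partner(lattice, col, cell_thirds, fid)
            if pcol >= 0 and pth in sg2[pcol]:
                sharing.append((pcol, pth))
        classes.append(TTJ if len(sharing) >= 3 else BTJ)
        cells.append(tuple(sharing))
    vkeys, ekeys = _ring_keys(lattice, ring.vertices_int)
    # tricellular points at ring vertices: ≥3 barrier cells meet there
    center = lattice.cell_center_int(col, cell_thirds)
    ttj_flags = []
    for vint in ring.vertices_int:
        count = 1
        # the three faces of the owning cell meeting at this vertex
        vid = _canon_vertex_id(vint - center)
        for fid in _VERT_FACES[vid]:
            pcol, pth = face_partner(lattice, col, cell_thirds, fid)
            if pcol >= 0 and pth in sg2[pcol]:
                count += 1
        ttj_flags.append(count >= 3)
    return TJPolygon(
        poly_id=poly_id, column=col, kind=kind, vertices=ring.vertices,
        seam_classes=classes, seam_cells=cells, edge_keys=ekeys,
        vertex_keys=vkeys, pair_id=pair_id, ttj_vertex_flags=ttj_flags,
    )


_CANON_LOOKUP: dict[tuple[int, int, int], int] = {}


def _canon_vertex_id(v: np.ndarray) -> int:
    if not _CANON_LOOKUP:
        from .geometry import _CANON_VERTS
        for i, u in enumerate(_CANON_VERTS):
            _CANON_LOOKUP[tuple(int(x) for x in u)] = i
    return _CANON_LOOKUP[tuple(int(x) for x in v)]


def coverage(snapshot: Snapshot, col: int, top_thirds: int,
             sg2: list[set[int]] | None = None) -> list[bool]:
    """Which of the six upper contact faces of the top cell of ``col`` are
    held by a neighbouring barrier cell (order UP_DIRS + DOWN_DIRS)."""
    lattice = snapshot.lattice
    if sg2 is None:
        sg2 = _sg2_sets(snapshot)
    cov = []
    for d in range(6):
        ncol = int(lattice.neighbors[col, d])
        off = 1 if d < 3 else 2
        cov.append(ncol >= 0 and (top_thirds + off) in sg2[ncol])
    return cov


def extract_honeycomb(snapshot: Snapshot, lattice: ColumnLattice | None = None,
                      scale: float | None = None) -> TJGraph:
    """Build the TJ honeycomb graph from a simulation snapshot.

    Steady/waiting columns contribute one single-edged polygon (the apical
    ring of their barrier cell); transitioning columns contribute the
    exterior/interior nested pair.
    """
    lattice = lattice or snapshot.lattice
    if scale is not None and scale != lattice.scale:
        raise ValueError("scale is set on the lattice; rebuild it instead")
    sg2 = _sg2_sets(snapshot)
    tops = snapshot.top_thirds()
    polys: list[TJPolygon] = []
    pair_counter = 0
    for col in range(lattice.n_columns):
        top = int(tops[col])
        cov = coverage(snapshot, col, top, sg2)
        ring = apical_tj_ring(lattice, col, top, cov)
        if snapshot.phase[col] == TRANSITION:
            pid = pair_counter
            pair_counter += 1
            polys.append(_ring_to_polygon(lattice, ring, sg2, len(polys),
                                          "exterior", pid, top))
            inner = apical_tj_ring(lattice, col, top - 3, [True] * 6)
            polys.append(_ring_to_polygon(lattice, inner, sg2, len(polys),
                                          "interior", pid, top - 3))
        else:
            polys.append(_ring_to_polygon(lattice, ring, sg2, len(polys),
                                          "single", None, top))
    return TJGraph(polys, lattice, timestamp=snapshot.t, scale=lattice.scale)


# ---------------------------------------------------------------------------
# classification & audits
# ---------------------------------------------------------------------------

@dataclass
class PairFacts:
    exterior: TJPolygon
    interior: TJPolygon
    area_exterior: float
    area_interior: float
    z_exterior: float
    z_interior: float
    nested: bool


def classify_double_edged(graph: TJGraph, strict: bool = True) -> list[PairFacts]:
    """Geometry facts for every exterior/interior pair.

    For each pair the interior must be smaller, lower, and nested within the
    exterior in the en face projection; with ``strict`` a violation raises.
    """
    out = []
    for ext, inner in graph.pairs:
        nested = ext.shapely().buffer(1e-9).contains(inner.shapely())
        facts = PairFacts(ext, inner, ext.enface_area, inner.enface_area,
                          ext.mean_z, inner.mean_z, nested)
        if strict and not (nested and facts.area_interior < facts.area_exterior
                           and facts.z_interior < facts.z_exterior):
            raise ValueError(
                f"double-edged pair on column {ext.column} violates the "
                "nested-smaller-lower invariant")
        out.append(facts)
    return out


@dataclass
class ContinuityReport:
    ok: bool
    uncovered_columns: list[int]
    unmatched_edges: int
    coverage_defect: float | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def barrier_continuity(graph: TJGraph, geometric: bool = False,
                       tol: float = 1e-6) -> ContinuityReport:
    """Audit barrier homeostasis of the honeycomb.

    Structural audit: every column carries at least one closed displayed
    polygon, and every displayed seam is shared — as an identical 3D segment
    — by exactly two displayed polygons, so the tiling has no holes.  With
    ``geometric=True`` the en face union of displayed polygons is also
    checked to cover the periodic domain within ``tol`` of its area.
    """
    lattice = graph.lattice
    bad_cols: set[int] = set()
    for col in range(lattice.n_columns):
        if not any(p.displayed and p.kind != "interior"
                   for p in graph.column_polygons(col)):
            bad_cols.add(col)
    unmatched = 0
    for key, owners in graph._edge_index.items():
        if len(owners) != 2:
            unmatched += 1
            for pid in owners:
                bad_cols.add(graph.polygon(pid).column)
    defect = None
    if geometric and lattice.periodic:
        a1, a2 = lattice.inplane_vectors
        shapes = []
        for p in graph.polygons:
            if p.kind == "interior":
                continue
            base = p.shapely()
            for u in (-1, 0, 1):
                for v in (-1, 0, 1):
                    off = u * lattice.nx * a1 + v * lattice.ny * a2
                    shapes.append(Polygon(p.vertices[:, :2] + off))
        union = unary_union(shapes)
        # central domain parallelogram
        corners = np.array([[0, 0], lattice.nx * a1, lattice.nx * a1 + lattice.ny * a2,
                            lattice.ny * a2])
        domain = Polygon(corners)
        defect = domain.difference(union).area / domain.area
        if defect > tol:
            bad_cols.add(-1)
    ok = not bad_cols and unmatched == 0 and (defect is None or defect <= tol)
    return ContinuityReport(ok, sorted(bad_cols), unmatched, defect)


def neighbors_of_polygon(graph: TJGraph, poly_id: int) -> list[int]:
    """Displayed polygons sharing a seam or a seam vertex with the query.

    An interior polygon is nested below the tiling; its neighbourhood is
    that of its exterior partner.  The partner itself is never listed as a
    neighbour of either member of the pair.
    """
    p = graph.polygon(poly_id)
    if p.kind == "interior":
        ext = next(e for e, i in graph.pairs if i.poly_id == poly_id)
        exclude = {poly_id, ext.poly_id}
        p = ext
    else:
        exclude = {poly_id}
        if p.pair_id is not None:
            inner = next(i for e, i in graph.pairs if e.poly_id == poly_id)
            exclude.add(inner.poly_id)
    found: set[int] = set()
    for k in p.vertex_keys:
        found.update(graph._vertex_index.get(k, []))
    for k in p.edge_keys:
        found.update(graph._edge_index.get(k, []))
    return sorted(found - exclude)
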