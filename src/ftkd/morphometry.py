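"""Morphometric measurements on TJ honeycombs.

Implements the measurement conventions used for the en face statistics:
shoelace areas of the en face projections (with the single-edged polygons'
overlap with neighbouring exterior polygons included, not clipped), polygon
Z as the mean of vertex Z, relative Z within octets of one double-edged
pair plus its six adjacent single-edged polygons, random square sampling
windows with centroid membership, and per-assay double-edged percentages
summarized as mean ± SEM across assays.

The same functions apply to simulated and synthetic honeycombs; areas are
in µm² once the lattice carries a µm scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .honeycomb import TJGraph, TJPolygon, neighbors_of_polygon

__all__ = [
    "polygon_area", "polygon_z", "relative_z", "sample_windows",
    "double_edged_percent", "collect_octets", "detect_double_edged",
    "area_scale_for_target", "class_area_stats", "SummaryStats", "Octet",
]

#: mean single-edged polygon area observed in mouse-ear whole mounts, µm²
TARGET_SINGLE_AREA = 905.8
#: sampling-window area used for the en face counts, µm²
WINDOW_AREA = 15376.0


def polygon_area(polygon: TJPolygon | np.ndarray,
                 convention: str = "include_overlap",
                 graph: TJGraph | None = None) -> float:
    """En face (shoelace) area of a closed polygon.

    ``include_overlap`` (the measurement convention used for single-edged
    polygons) takes the full area inside the polygon's own ring, including
    any region it shares with adjacent exterior polygons.  ``plain`` clips
    the polygon to its exclusive en face territory (requires ``graph``).
    On exact lattice honeycombs the ring abuts the exterior outline, so the
    two conventions coincide; they differ on jittered meshes.
    """
    if convention not in ("plain", "include_overlap"):
        raise ValueError(f"unknown convention {convention!r}")
    if isinstance(polygon, TJPolygon):
        shp = polygon.shapely()
    else:
        pts = np.asarray(polygon, dtype=float)
        if len(pts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        shp = Polygon(pts[:, :2])
    if not shp.is_valid:
        raise ValueError("polygon ring is not a simple closed cycle")
    if convention == "include_overlap" or graph is None:
        return shp.area
    if isinstance(polygon, TJPolygon) and polygon.kind == "single":
        for pid in neighbors_of_polygon(graph, polygon.poly_id):
            q = graph.polygon(pid)
            if q.kind == "exterior":
                shp = shp.difference(q.shapely())
    return shp.area


def polygon_z(polygon: TJPolygon | np.ndarray) -> float:
    """Z position of a polygon: the average Z of its vertices."""
    pts = polygon.vertices if isinstance(polygon, TJPolygon) else np.asarray(polygon, float)
    if len(pts) == 0:
        raise ValueError("empty polygon")
    return float(np.mean(pts[:, 2]))


def relative_z(z_values: np.ndarray) -> np.ndarray:
    """Relative Z within an octet: each Z minus the octet mean.

    An octet is one exterior + one interior + the six adjacent single-edged
    polygons; the outputs sum to zero by construction.
    """
    z = np.asarray(z_values, dtype=float)
    if z.shape != (8,):
        raise ValueError(f"an octet has exactly 8 polygons, got {z.shape}")
    return z - z.mean()


@dataclass
class Octet:
    """One double-edged pair with its six adjacent single-edged polygons."""

    column: int
    area_exterior: float
    area_interior: float
    areas_single: np.ndarray
    z_exterior: float
    z_interior: float
    z_single: np.ndarray

    @property
    def z_relative(self) -> np.ndarray:
        """Relative Z in the order exterior, interior, then the six singles."""
        return relative_z(np.concatenate(
            [[self.z_exterior, self.z_interior], self.z_single]))


def collect_octets(graph: TJGraph, convention: str = "include_overlap") -> list[Octet]:
    """All clean octets of a honeycomb.

    Pairs whose neighbourhood is not six single-edged polygons (e.g. a
    second double-edged pair next door) are skipped, as in the manual
    en face scoring.
    """
    out = []
    for ext, inner in graph.pairs:
        nb = [graph.polygon(i) for i in neighbors_of_polygon(graph, ext.poly_id)]
        if len(nb) != 6 or any(p.kind != "single" for p in nb):
            continue
        out.append(Octet(
            column=ext.column,
            area_exterior=polygon_area(ext, convention, graph),
            area_interior=polygon_area(inner, convention, graph),
            areas_single=np.array([polygon_area(p, convention, graph) for p in nb]),
            z_exterior=polygon_z(ext),
            z_interior=polygon_z(inner),
            z_single=np.array([polygon_z(p) for p in nb]),
        ))
    return out


def detect_double_edged(graph: TJGraph) -> list[tuple[int, int]]:
    """Detect nested (exterior, interior) pairs from geometry alone.

    A polygon is called interior when its en face centroid lies inside
    another polygon that is larger and higher; used to validate recovery of
    planted pairs on noisy synthetic meshes without consulting labels.
    """
    shapes = [(p, p.shapely()) for p in graph.polygons]
    pairs = []
    for p, sp in shapes:
        c = sp.centroid
        best = None
        for q, sq in shapes:
            if q.poly_id == p.poly_id:
                continue
            if sq.area > sp.area and q.mean_z > p.mean_z and sq.contains(c):
                if best is None or sq.area < best[1].area:
                    best = (q, sq)
        if best is not None:
            pairs.append((best[0].poly_id, p.poly_id))
    return pairs


def sample_windows(graph: TJGraph, n_windows: int, window_area: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Counts of single- and double-edged polygons in random square windows.

    Windows are axis-aligned squares of ``window_area`` placed uniformly on
    the periodic domain; a polygon belongs to a window when its en face
    centroid falls inside (centroids wrapped onto the torus).  Each nested
    pair counts once, through its exterior's centroid.
    """
    lattice = graph.lattice
    a1, a2 = lattice.inplane_vectors
    side = float(np.sqrt(window_area))
    # bounding box of the periodic domain
    corners = np.array([[0.0, 0.0], lattice.nx * a1,
                        lattice.nx * a1 + lattice.ny * a2, lattice.ny * a2])
    if side > (corners[:, 0].max() - corners[:, 0].min()) or \
       side > (corners[:, 1].max() - corners[:, 1].min()):
        raise ValueError("window larger than the domain")
    pts, kinds = [], []
    for p in graph.polygons:
        if p.kind == "interior":
            continue
        c = p.shapely().centroid
        pts.append([c.x, c.y])
        kinds.append("double" if p.kind == "exterior" else "single")
    pts = np.asarray(pts)
    kinds = np.asarray(kinds)
    # torus images so windows near an edge see the wrapped content; the
    # image radius must cover the window's reach beyond the domain
    t1, t2 = lattice.nx * a1, lattice.ny * a2
    reach = min(np.linalg.norm(t1), np.linalg.norm(t2))
    radius = 1 + int(np.ceil(side / reach))
    rng_r = range(-radius, radius + 1)
    images = [pts + u * t1 + v * t2 for u in rng_r for v in rng_r]
    all_pts = np.vstack(images)
    all_kinds = np.tile(kinds, len(images))
    rows = []
    for w in range(n_windows):
        u, v = rng.uniform(0, 1, 2)
        lo = u * lattice.nx * a1 + v * lattice.ny * a2
        inside = ((all_pts[:, 0] >= lo[0]) & (all_pts[:, 0] < lo[0] + side)
                  & (all_pts[:, 1] >= lo[1]) & (all_pts[:, 1] < lo[1] + side))
        k = all_kinds[inside]
        rows.append({"window": w, "n_single": int((k == "single").sum()),
                     "n_double": int((k == "double").sum())})
    return pd.DataFrame(rows)


def double_edged_percent(assay_counts: list[pd.DataFrame]) -> tuple[float, float, int]:
    """Mean ± SEM (%) of the double-edged percentage across assays.

    Each assay's percentage pools that assay's window counts:
    100 * doubles / (singles + doubles).
    """
    if not assay_counts:
        raise ValueError("need at least one assay")
    pcts = []
    for df in assay_counts:
        if len(df) == 0:
            raise ValueError("empty assay")
        s, d = df["n_single"].sum(), df["n_double"].sum()
        if s + d == 0:
            raise ValueError("assay windows contain no polygons")
        pcts.append(100.0 * d / (s + d))
    pcts = np.asarray(pcts)
    n = len(pcts)
    sem = float(pcts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(pcts.mean()), sem, n


def area_scale_for_target(mean_area_units: float,
                          target: float = TARGET_SINGLE_AREA) -> float:
    """µm-per-lattice-unit scale making a mean polygon area hit ``target``."""
    if mean_area_units <= 0:
        raise ValueError("mean area must be positive")
    return float(np.sqrt(target / mean_area_units))


def class_area_stats(graphs: list[TJGraph],
                     convention: str = "include_overlap") -> pd.DataFrame:
    """Mean, SEM and n of en face polygon area per class over honeycombs."""
    vals: dict[str, list[float]] = {"single": [], "exterior": [], "interior": []}
    zs: dict[str, list[float]] = {"single": [], "exterior": [], "interior": []}
    for g in graphs:
        for p in g.polygons:
            vals[p.kind].append(polygon_area(p, convention, g))
            zs[p.kind].append(polygon_z(p))
    rows = []
    for cls in ("exterior", "single", "interior"):
        for metric, data in (("area_um2", vals[cls]), ("z_um", zs[cls])):
            a = np.asarray(data)
            n = len(a)
            rows.append({
                "metric": metric, "class": cls,
                "mean": a.mean() if n else np.nan,
                "sem": a.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            })
    return pd.DataFrame(rows)


@dataclass
class SummaryStats:
    """Headline statistics of a set of simulated assays."""

    double_edged_percent_mean: float
    double_edged_percent_sem: float
    n_assays: int
    residence_mean_hr: float
    residence_sem_hr: float
    n_residence: int
    area_stats: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "double_edged_percent", "class": "all",
             "mean": self.double_edged_percent_mean,
             "sem": self.double_edged_percent_sem, "n": self.n_assays,
             "units": "%"},
            {"metric": "residence_time", "class": "all",
             "mean": self.residence_mean_hr, "sem": self.residence_sem_hr,
             "n": self.n_residence, "units": "hr"},
        ]
        df = self.area_stats.copy()
        df["units"] = np.where(df["metric"] == "area_um2", "um2", "um")
        return pd.concat([pd.DataFrame(rows), df], ignore_index=True)
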