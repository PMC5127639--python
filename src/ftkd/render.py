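"""En face rendering of TJ honeycombs.

Seams are drawn in the two junction styles (bicellular green, tricellular
purple) and cells are shaded into three height classes — a display binning
of the continuous column heights, as in the simulation movies.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import Trajectory
from .honeycomb import TJGraph, extract_honeycomb

__all__ = ["render_enface", "render_frames"]

_BTJ_COLOR = "#2ca02c"
_TTJ_COLOR = "#7b2fbe"
_FILLS = ["#fff3c9", "#ffd796", "#f5a35c"]  # low, mid, high


def render_enface(graph: TJGraph, path: str | Path, dpi: int = 120) -> Path:
    """Draw one honeycomb; the suffix of ``path`` picks SVG or PNG."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 7))
    tops = {}
    for p in graph.polygons:
        if p.kind != "interior":
            tops[p.column] = p.vertices[:, 2].max()
    heights = np.array(sorted(tops.values()))
    terciles = np.quantile(heights, [1 / 3, 2 / 3]) if len(heights) > 2 else [0, 0]
    for p in graph.polygons:
        xy = p.vertices[:, :2]
        if p.kind != "interior":
            h = tops[p.column]
            fill = _FILLS[int(np.searchsorted(terciles, h))]
            patch = plt.Polygon(xy, closed=True, facecolor=fill,
                                edgecolor="none", zorder=1)
            patch.set_gid(f"cell-{p.column}-{p.kind}")
            ax.add_patch(patch)
        m = len(xy)
        for k in range(m):
            a, b = xy[k], xy[(k + 1) % m]
            is_ttj = p.seam_classes[k] == "tTJ"
            (ln,) = ax.plot([a[0], b[0]], [a[1], b[1]],
                            color=_TTJ_COLOR if is_ttj else _BTJ_COLOR,
                            lw=2.0 if is_ttj else 1.2, zorder=3 if is_ttj else 2)
            ln.set_gid(f"seam-{p.kind}-{p.seam_classes[k]}")
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)" if graph.scale != 1.0 else "x (lattice units)")
    ax.set_ylabel("y (µm)" if graph.scale != 1.0 else "y (lattice units)")
    ax.autoscale_view()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def render_frames(traj: Trajectory, out_dir: str | Path,
                  t_start: float, t_stop: float, dpi: int = 80) -> list[Path]:
    """One PNG per recorded frame with t_start < t <= t_stop."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(traj.n_frames):
        t = traj.times[k]
        if t_start < t <= t_stop + 1e-9:
            g = extract_honeycomb(traj.snapshot(k))
            paths.append(render_enface(g, out_dir / f"frame_{k:05d}.png", dpi=dpi))
    return paths
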