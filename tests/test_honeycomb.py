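"""The TJ honeycomb graph: seam classes, nesting, continuity, adjacency."""

import numpy as np
import pytest
from ftkd.engine import SimConfig, TRANSITION, run
from ftkd.geometry import make_canonical_tkd
from ftkd.honeycomb import (barrier_continuity, classify_double_edged,
                            extract_honeycomb, neighbors_of_polygon)
from ftkd.synthetic import _hexprism


def brute_force_sharing(graph, polygon, edge_idx):
    """Independent oracle: count barrier cells whose polyhedron contains
    both endpoints of a seam, scanning all nearby cells exhaustively."""
    lattice = graph.lattice
    m = len(polygon.vertices)
    snap = graph._snapshot
    a = polygon._vints[edge_idx]
    b = polygon._vints[(edge_idx + 1) % m]
    ka, kb = map(tuple, lattice.wrap_int(np.stack([a, b])))
    count = []
    for col in range(lattice.n_columns):
        for t in snap.sg2_heights(col):
            cell = make_canonical_tkd(lattice.flatten_ratio, lattice.scale,
                                      lattice.cell_center_int(col, t))
            vs = set(map(tuple, lattice.wrap_int(cell.vertices_int)))
            if ka in vs and kb in vs:
                count.append((col, t))
    return count


@pytest.fixture(scope="module")
def transition_graph():
    """A honeycomb with several transitioning columns, with its snapshot and
    integer ring coordinates attached for oracle checks."""
    traj = run(SimConfig(seed=11, duration=36.0, n_cols_x=6, n_cols_y=6))
    snap = None
    for k in range(traj.n_frames - 1, -1, -1):
        if (traj.phases[k] == TRANSITION).sum() >= 2:
            snap = traj.snapshot(k)
            break
    assert snap is not None
    g = extract_honeycomb(snap)
    g._snapshot = snap
    # keep integer coords for the oracle
    from ftkd.geometry import apical_tj_ring
    from ftkd.honeycomb import coverage, _sg2_sets
    sg2 = _sg2_sets(snap)
    tops = snap.top_thirds()
    for p in g.polygons:
        t = int(tops[p.column]) if p.kind != "interior" else int(tops[p.column]) - 3
        cov = coverage(snap, p.column, t, sg2) if p.kind != "interior" else [True] * 6
        p._vints = apical_tj_ring(g.lattice, p.column, t, cov).vertices_int
    return g


class TestExtraction:
    def test_all_steady_base_case(self):
        """Initial lattice: one polygon per column, no displayed tricellular
        seams, but tricellular points recorded at polygon vertices."""
        lat_cfg = SimConfig(seed=1, duration=24.0, n_cols_x=6, n_cols_y=6)
        traj = run(lat_cfg)
        g = extract_honeycomb(traj.snapshot(0))
        assert len(g.polygons) == 36
        assert all(p.kind == "single" for p in g.polygons)
        assert sum(c == "tTJ" for p in g.polygons for c in p.seam_classes) == 0
        assert any(any(p.ttj_vertex_flags) for p in g.polygons)

    def test_one_transition_gives_one_nested_pair(self, column_pair):
        graph, host = column_pair
        assert len(graph.pairs) == 1
        ext, inner = graph.pairs[0]
        assert ext.column == inner.column == host
        assert all(c == "tTJ" for c in inner.seam_classes)
        assert inner.n_edges == 6

    def test_ttj_seams_shared_by_exactly_three(self, transition_graph):
        """Every tricellular seam's sharing set has cardinality 3, checked
        against the exhaustive cell-incidence oracle."""
        g = transition_graph
        checked = 0
        for p in g.polygons:
            for k, cls in enumerate(p.seam_classes):
                if cls == "tTJ":
                    assert len(p.seam_cells[k]) == 3
                    oracle = brute_force_sharing(g, p, k)
                    assert sorted(oracle) == sorted(p.seam_cells[k])
                    checked += 1
        assert checked >= 12

    def test_btj_seams_shared_by_exactly_two(self, transition_graph):
        g = transition_graph
        for p in g.polygons:
            for k, cls in enumerate(p.seam_classes):
                if cls == "bTJ":
                    assert len(p.seam_cells[k]) == 2

    def test_fraction_matches_engine(self, transition_graph):
        g = transition_graph
        snap = g._snapshot
        assert g.double_edged_fraction == pytest.approx(
            snap.double_edged_fraction)

    def test_displayed_polygons_tile_domain(self, transition_graph):
        g = transition_graph
        total = sum(p.enface_area for p in g.polygons if p.kind != "interior")
        assert total == pytest.approx(g.lattice.domain_area, rel=1e-9)


class TestClassification:
    def test_pairs_nested_smaller_lower(self, transition_graph):
        facts = classify_double_edged(transition_graph)
        assert facts
        for f in facts:
            assert f.area_interior < f.area_exterior
            assert f.z_interior < f.z_exterior
            assert f.nested

    def test_all_steady_gives_empty_list(self):
        traj = run(SimConfig(seed=1, duration=24.0, n_cols_x=6, n_cols_y=6))
        g = extract_honeycomb(traj.snapshot(0))
        assert classify_double_edged(g) == []


class TestContinuity:
    def test_structural_and_geometric_on_simulated_frames(self, short_run):
        for k in range(0, short_run.n_frames, 151):
            g = extract_honeycomb(short_run.snapshot(k))
            rep = barrier_continuity(g, geometric=True)
            assert rep.ok, (k, rep)

    def test_deleted_seam_reported(self, column_pair):
        graph, host = column_pair
        victim = next(p for p in graph.polygons if p.kind == "single")
        victim.edge_keys[0] = b"deleted"
        import ftkd.honeycomb as H
        g2 = H.TJGraph(graph.polygons, graph.lattice)
        rep = barrier_continuity(g2)
        assert not rep.ok
        assert victim.column in rep.uncovered_columns

    def test_hexprism_slide_breaks_barrier(self):
        """Simple columnar (hexagonal prism) packing: sliding one column
        upward tears its seams out of the shared plane."""
        assert barrier_continuity(_hexprism(slide=0.0, slid_column=None),
                                  geometric=True).ok
        rep = barrier_continuity(_hexprism(slide=0.5))
        assert not rep.ok
        assert rep.unmatched_edges > 0
        assert 4 in rep.uncovered_columns


class TestNeighbors:
    def test_double_edged_pair_has_six_single_neighbors(self, column_pair):
        graph, host = column_pair
        ext, inner = graph.pairs[0]
        nb = neighbors_of_polygon(graph, ext.poly_id)
        assert len(nb) == 6
        assert all(graph.polygon(i).kind == "single" for i in nb)
        assert neighbors_of_polygon(graph, inner.poly_id) == nb

    def test_steady_polygon_has_six_neighbors(self):
        traj = run(SimConfig(seed=1, duration=24.0, n_cols_x=6, n_cols_y=6))
        g = extract_honeycomb(traj.snapshot(0))
        for p in g.polygons[:8]:
            assert len(neighbors_of_polygon(g, p.poly_id)) == 6

    def test_adjacency_symmetric(self, transition_graph):
        g = transition_graph
        ids = [p.poly_id for p in g.polygons if p.kind != "interior"]
        for i in ids:
            for j in neighbors_of_polygon(g, i):
                back = neighbors_of_polygon(g, j)
                pj = g.polygon(j)
                # a pair's members share one neighbourhood
                assert i in back or (pj.pair_id is not None)

    def test_unknown_polygon_raises(self, transition_graph):
        with pytest.raises(KeyError):
            transition_graph.polygon(10_000)


class TestEdgeByEdgeReplacement:
    def test_polygon_grows_stepwise_between_own_transitions(self, short_run):
        """Following one column through a full cycle: its displayed polygon
        area never shrinks between its own transitions, and the seam set
        changes by a few seams at a time as neighbours turn over."""
        traj = short_run
        ev = traj.events
        col = int(ev[ev.event == "transition_start"].column_id.iloc[0])
        starts = ev[(ev.event == "transition_start")
                    & (ev.column_id == col)].time_hr.to_numpy()
        assert len(starts) >= 2
        # track the incoming cell from the end of its promoting transition
        # to the start of its own exit
        t0 = starts[0] + traj.config.disappearance_duration
        t1 = starts[1]
        frames = [k for k in range(traj.n_frames)
                  if t0 < traj.times[k] <= t1 - traj.config.dt / 2]
        prev_area, prev_keys = None, None
        for k in frames[::3]:
            g = extract_honeycomb(traj.snapshot(k))
            p = next(q for q in g.column_polygons(col) if q.kind != "interior")
            area = p.enface_area
            keys = set(p.edge_keys)
            if prev_area is not None:
                assert area >= prev_area - 1e-9
                gained = len(keys - prev_keys)
                lost = len(prev_keys - keys)
                assert gained <= 6 and lost <= 6
            prev_area, prev_keys = area, keys
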