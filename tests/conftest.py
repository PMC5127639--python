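"""Shared fixtures: simulations are run once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from ftkd.engine import SimConfig, Snapshot, run
from ftkd.honeycomb import extract_honeycomb
from ftkd.morphometry import area_scale_for_target
from ftkd.synthetic import make_fixture


@pytest.fixture(scope="session")
def default_runs():
    """Five seeds at the default study conditions (21x21 periodic columns,
    wait U(0, 9.6 hr), disappearance 2.4 hr, dt 7.2 min, 48 hr burn-in,
    480 hr measured)."""
    out = []
    for seed in range(1, 6):
        config = SimConfig(seed=seed)
        out.append(run(config))
    return out


@pytest.fixture(scope="session")
def short_run():
    """One default-parameter run with a shorter measurement window, used
    where honeycombs must be extracted frame by frame."""
    return run(SimConfig(seed=7, duration=48.0))


@pytest.fixture(scope="session")
def sampled_graphs(default_runs):
    """Honeycombs extracted every ~12 hr from the first default run."""
    traj = default_runs[0]
    return [extract_honeycomb(s) for s in traj.snapshots(stride=100)]


@pytest.fixture(scope="session")
def calibrated_graphs(default_runs):
    """Micrometre-scaled honeycombs (mean single-edged area = 905.8 µm²)."""
    traj = default_runs[0]
    snaps = list(traj.snapshots(stride=100))
    raw = [extract_honeycomb(s) for s in snaps]
    mean_single = float(np.mean([p.enface_area for g in raw for p in g.singles]))
    scale = area_scale_for_target(mean_single)
    lattice = traj.config.lattice(scale=scale)
    return [extract_honeycomb(Snapshot(s.t, s.phase, s.h3, lattice))
            for s in snaps]


@pytest.fixture()
def column_pair():
    graph, host = make_fixture("column_pair")
    return graph, host


@pytest.fixture()
def star7():
    return make_fixture("star7")
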