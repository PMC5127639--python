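#!/usr/bin/env python
"""Barrier continuity: interdigitated f-TKD columns vs hexagonal prisms.

Audits every extracted frame of a default run for barrier continuity (all
seams of the displayed honeycomb shared as identical 3D segments, en face
coverage complete) and contrasts it with the hexagonal-prism straw man,
where sliding one column upward — the only way a cell can cross the
barrier in a simple columnar packing — tears its seams out of the common
apical plane.  Expected outcome: the f-TKD honeycomb never breaks during
turnover; the slid hexagonal prism always does.
"""

from pathlib import Path

import pandas as pd

from ftkd.engine import SimConfig, run
from ftkd.honeycomb import barrier_continuity, extract_honeycomb
from ftkd.synthetic import _hexprism

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = SimConfig(seed=1, duration=96.0)
    traj = run(config)
    n_frames = n_ok = 0
    for snap in traj.snapshots(stride=5):
        rep = barrier_continuity(extract_honeycomb(snap))
        n_frames += 1
        n_ok += rep.ok
    hex_ok = barrier_continuity(_hexprism(slide=0.0, slid_column=None)).ok
    hex_slid = barrier_continuity(_hexprism(slide=0.5))
    df = pd.DataFrame([
        {"lattice": "f-TKD turnover", "frames": n_frames,
         "continuous_frames": n_ok, "broken": n_frames - n_ok},
        {"lattice": "hex prisms (static)", "frames": 1,
         "continuous_frames": int(hex_ok), "broken": int(not hex_ok)},
        {"lattice": "hex prisms (one column slid)", "frames": 1,
         "continuous_frames": int(hex_slid.ok), "broken": int(not hex_slid.ok)},
    ])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "barrier_comparison.csv", index=False)
    print(df.to_string(index=False))
    if not hex_slid.ok:
        print("\nhex prism slide tears seams at columns:",
              hex_slid.uncovered_columns)


if __name__ == "__main__":
    main()
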