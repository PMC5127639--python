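#!/usr/bin/env python
"""Recovery of planted double-edged pairs from noisy synthetic honeycombs.

Generates microscopy-like meshes (mean single-edged area 905.8 µm²,
planted pair rate 9.8%) at increasing vertex jitter and scores the
geometric pair detector (nested, smaller, lower) against the planted
truth.  Expected outcome: exact recovery without noise, and >= 99%
agreement at the 0.5 µm localization jitter typical of the imaging the
mesh emulates.
"""

from pathlib import Path

import pandas as pd

from ftkd.morphometry import detect_double_edged
from ftkd.synthetic import SynthConfig, make_noisy_honeycomb

OUT = Path(__file__).resolve().parents[1] / "results"


def score(jitter: float, seed: int) -> dict:
    g, truth = make_noisy_honeycomb(SynthConfig(
        jitter_xy_um=jitter, jitter_z_um=jitter, seed=seed))
    detected = {g.polygon(e).column for e, _ in detect_double_edged(g)}
    planted = set(truth[truth.planted_double].column)
    n = len(truth)
    agree = n - len(detected.symmetric_difference(planted))
    return {"jitter_um": jitter, "seed": seed, "n_columns": n,
            "n_planted": len(planted), "n_detected": len(detected),
            "percent_agreement": 100.0 * agree / n}


def main() -> None:
    rows = [score(j, s) for j in (0.0, 0.5, 1.0, 2.0) for s in (1, 2, 3)]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "synthetic_recovery.csv", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    by_j = df.groupby("jitter_um")["percent_agreement"].mean()
    print("\nmean agreement by jitter (µm):")
    print(by_j.to_string(float_format="%.2f"))


if __name__ == "__main__":
    main()
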