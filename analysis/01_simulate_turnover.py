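#!/usr/bin/env python
"""Steady-state turnover statistics of the default model.

Runs the default simulation (waiting uniform on [0, 9.6] hr, disappearance
2.4 hr, dt 7.2 min, periodic 21x21 columns, 48 hr burn-in + 480 hr
measured) for five seeds and tabulates the double-edged percentage and the
barrier residence time.  Expected outcome: ~9.9% double-edged and a ~24 hr
mean turnover cycle, the pair of observations the waiting-time bound was
chosen to reproduce.
"""

from pathlib import Path

import pandas as pd

from ftkd.engine import SimConfig, run, double_edged_fraction, residence_times

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for seed in range(1, 6):
        config = SimConfig(seed=seed)
        traj = run(config)
        res = residence_times(traj.events, config.burn_in)
        res_full = residence_times(traj.events, config.burn_in, "completion")
        rows.append({
            "seed": seed,
            "double_edged_percent": 100 * double_edged_fraction(traj),
            "mean_residence_hr": res.mean(),
            "mean_residence_completion_hr": res_full.mean(),
            "n_turnovers": len(res),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "turnover_summary.csv", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    print(f"\nmean double-edged: {df.double_edged_percent.mean():.2f}% "
          f"(SEM {df.double_edged_percent.sem():.2f})")
    print(f"mean residence (cycle): {df.mean_residence_hr.mean():.2f} hr; "
          f"to completion: {df.mean_residence_completion_hr.mean():.2f} hr")
    print("renewal check: disappearance / mean residence =",
          f"{100 * 2.4 / df.mean_residence_hr.mean():.2f}%")


if __name__ == "__main__":
    main()
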