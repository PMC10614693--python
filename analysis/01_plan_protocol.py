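#!/usr/bin/env python
"""Plan the FUS treatment and tabulate the protocol dosimetry.

Builds the 5x5 / 0.5 mm steered-focus grid at the 55 mm geometric focus,
the 5 Hz x 2 min burst schedule, and the derived dosimetry numbers
(derated pressures, mechanical indices of the monitoring pulses,
insonified volume, microbubble dose).  Writes:

    results/treatment_plan.txt      key-value plan + position list
    results/grid_positions.csv      x, y, z per steered focus
    results/protocol_summary.csv    one row per dosimetry quantity
"""

import argparse
from pathlib import Path

import pandas as pd

from sonopet import protocol


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    plan = protocol.plan_treatment_grid((0.0, 0.0, 55.0), rows=5, cols=5, step_mm=0.5)
    sched = protocol.build_burst_schedule(plan, burst_ms=1.0, rep_hz=5.0, total_s=120.0)

    (args.outdir / "treatment_plan.txt").write_text(
        plan.to_config_text() + sched.to_config_text()
    )
    (args.outdir / "grid_positions.csv").write_text(plan.positions_csv())

    rows = [
        ("grid_positions", plan.n_positions, ""),
        ("bursts_per_point", sched.bursts_per_point(plan.n_positions), ""),
        ("sweep_duration_ms", sched.sweep_duration_ms, "ms"),
        ("total_bursts", sched.n_bursts, ""),
        ("insonified_volume_mm3", round(protocol.treated_volume(2.5, 2.5, 2.7)), "mm^3"),
        ("mb_dose_per_kg", protocol.mb_dose_per_kg(5e6, 20.0), "MB/kg"),
        ("mi_bmode_10p4mhz", round(protocol.mechanical_index(136.0, 10.4), 2), ""),
        ("mi_cps_5p2mhz", round(protocol.mechanical_index(250.0, 5.2), 2), ""),
    ]
    for pnp in (420.0, 600.0, 740.0):
        rows.append(
            (f"derated_pnp_from_{pnp:.0f}kpa", round(protocol.derate_pnp(pnp, 0.20)), "kPa")
        )
    df = pd.DataFrame(rows, columns=["quantity", "value", "units"])
    df.to_csv(args.outdir / "protocol_summary.csv", index=False)
    print(df.to_string(index=False))
    print(
        f"\n{plan.n_positions}-point grid, {sched.bursts_per_point(plan.n_positions)} "
        f"bursts per point, one sweep every {1e3 / sched.grid_repetition_rate_hz:.0f} ms."
    )


if __name__ == "__main__":
    main()
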