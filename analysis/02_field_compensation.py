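#!/usr/bin/env python
"""Simulate the steered focal field and estimate drive compensation.

Runs the CW Rayleigh field model for the (synthetic-layout) 128-element
therapeutic array: computes per-position compensation factors for the 5x5
treatment grid, verifies that compensated focal peaks are equalized, and
measures the -6 dB focal dimensions at the geometric focus.  Writes:

    results/compensation_table.csv   position, factor
    results/focal_dimensions.csv     -6 dB axial/transverse extents (mm)
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sonopet import field_model as fm
from sonopet import protocol


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    array = protocol.therapeutic_array()
    medium = fm.Medium()
    plan = protocol.plan_treatment_grid((0.0, 0.0, 55.0), 5, 5, 0.5)

    table = fm.compensation_factors(array, plan, medium)
    (args.outdir / "compensation_table.csv").write_text(table.to_csv())

    peaks = []
    for pos, f in zip(plan.focus_positions_mm, table.factors):
        grid = fm.EvaluationGrid.around(pos, (0.4, 0.4, 0.8), 0.1)
        fld = fm.simulate_steered_field(array, pos, medium, grid,
                                        drive=f * np.ones(array.n_elements))
        peaks.append(fld.peak()[0])
    spread = max(peaks) / min(peaks)

    grid = fm.EvaluationGrid.around((0, 0, 55.0), (2.0, 2.0, 6.0), 0.05)
    field = fm.simulate_steered_field(array, (0, 0, 55.0), medium, grid)
    axial, tx, ty = fm.focal_dimensions(field, -6.0)
    pd.DataFrame(
        [{"axial_mm": axial, "transverse_x_mm": tx, "transverse_y_mm": ty}]
    ).to_csv(args.outdir / "focal_dimensions.csv", index=False)

    print(f"compensation factors: {table.factors.min():.6f} .. {table.factors.max():.6f}")
    print(f"post-compensation focal peak spread (max/min): {spread:.6f}")
    print(f"-6 dB focal dimensions: {axial:.2f} mm axial, "
          f"{tx:.2f} x {ty:.2f} mm transverse")


if __name__ == "__main__":
    main()
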