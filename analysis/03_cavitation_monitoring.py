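#!/usr/bin/env python
"""Synthesize cavitation recordings, map them, and summarize band powers.

Emulates the monitoring arm of a three-pressure exposure series: stable
(harmonic) emissions at all pressures with broadband content growing with
drive pressure.  For the reference pressure, reconstructs harmonic- and
broadband-band PAM maps and localizes the source against the set focus;
for all groups, computes PS_F traces, group averages and the
stable/inertial classification.  Writes:

    results/pam_map_harmonic.csv      cumulative harmonic-band map
    results/pam_localization.csv      peak vs set focus per seed
    results/spectrum_traces.csv       PS_F long-format traces
    results/cavitation_summary.csv    per-group ratio and classification
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sonopet import cavitation, io, pam, protocol, synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    imaging = protocol.imaging_array()
    focus = (0.5, 0.0, 55.0)

    # PAM localization at the reference pressure, three seeds
    loc_rows = []
    for i in range(3):
        src = synthetic.CavitationSource(position_mm=focus, kind="stable")
        rf = synthetic.make_cavitation_rf([src], imaging, n_bursts=1, noise_sd=0.1,
                                          seed=args.seed + i, pressure_kpa=600.0)
        image = pam.asm_pam(rf, pam.harmonic_bands(), depth_range_mm=(45.0, 65.0))
        lat, dep = pam.localize_max(image)
        d_lat, d_ax = pam.localization_offset((lat, dep), (focus[0], focus[2]))
        loc_rows.append({"seed": args.seed + i, "peak_lateral_mm": lat,
                         "peak_depth_mm": dep, "offset_lateral_mm": d_lat,
                         "offset_axial_mm": d_ax})
        if i == 0:
            io.pam_to_csv(image, args.outdir / "pam_map_harmonic.csv")
    loc = pd.DataFrame(loc_rows)
    loc.to_csv(args.outdir / "pam_localization.csv", index=False)

    # Band-power traces across the pressure series (small fast configs)
    groups = {420.0: 0.05, 600.0: 0.1, 740.0: 0.4}  # broadband level per pressure
    traces_h, traces_b = [], []
    for pressure, level in groups.items():
        for animal in range(3):
            src = synthetic.CavitationSource(
                position_mm=focus, kind="mixed", broadband_level=level,
            )
            rf = synthetic.make_cavitation_rf(
                [src], imaging, n_bursts=10, duration_ms=0.2, noise_sd=0.05,
                seed=args.seed + int(pressure) + animal, pressure_kpa=pressure,
                animal_id=f"m{pressure:.0f}_{animal}",
            )
            tr = cavitation.trace(rf)
            traces_h.append(tr["harmonic"])
            traces_b.append(tr["broadband"])
    cavitation.traces_to_frame(traces_h + traces_b).to_csv(
        args.outdir / "spectrum_traces.csv", index=False
    )

    avg_h = cavitation.average_traces(traces_h)
    avg_b = cavitation.average_traces(traces_b)
    rows = []
    for pressure in groups:
        s = cavitation.stable_inertial_summary(
            cavitation.SpectrumTrace("harmonic", avg_h[pressure].values,
                                     avg_h[pressure].burst_times_s, pressure_kpa=pressure),
            cavitation.SpectrumTrace("broadband", avg_b[pressure].values,
                                     avg_b[pressure].burst_times_s, pressure_kpa=pressure),
        )
        rows.append({
            "pressure_kpa": pressure,
            "mean_harmonic_ps": avg_h[pressure].values.mean(),
            "mean_broadband_ps": avg_b[pressure].values.mean(),
            "median_ratio": float(np.nanmedian(s.ratio)),
            "classification": s.classification,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(args.outdir / "cavitation_summary.csv", index=False)

    print(loc.to_string(index=False))
    print()
    print(summary.to_string(index=False))
    print("\nBroadband PS grows with drive pressure; localization offsets stay "
          "within the PAM point-spread scale.")


if __name__ == "__main__":
    main()
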