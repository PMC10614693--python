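#!/usr/bin/env python
"""ΔΔCt quantification of synthetic reporter-gene qPCR designs.

Generates Ct tables for the two transduction comparisons the pipeline
supports — treated hemisphere vs no-FUS controls (102-fold design) and
treated vs contralateral hemisphere (12.5-fold design) — at zero and
realistic Ct noise, and recovers the fold changes by ΔΔCt.  Writes:

    results/qpcr_tables.csv       generated Ct values (noisy designs)
    results/ddct_fold_changes.csv recovered fold changes per design
"""

import argparse
from pathlib import Path

import pandas as pd

from sonopet import pet_quant as pq
from sonopet import synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    designs = {
        "treated_vs_no_fus": 102.0,
        "treated_vs_contralateral": 12.5,
    }
    rows, tables = [], []
    for name, fold in designs.items():
        for noise in (0.0, 0.2):
            table = synthetic.make_qpcr_ct(
                {"reference": 1.0, "treated": fold},
                noise_sd=noise, n_per_group=6, seed=args.seed,
            )
            recovered = pq.delta_delta_ct(table, "treated", "reference")
            rows.append({
                "design": name, "configured_fold": fold,
                "ct_noise_sd": noise, "recovered_fold": round(recovered, 2),
            })
            if noise > 0:
                tables.append(table.assign(design=name))
    pd.concat(tables).to_csv(args.outdir / "qpcr_tables.csv", index=False)
    out = pd.DataFrame(rows)
    out.to_csv(args.outdir / "ddct_fold_changes.csv", index=False)
    print(out.to_string(index=False))
    print("\nNoise-free designs are recovered exactly; noisy designs scatter "
          "around the configured fold on the log2 scale.")


if __name__ == "__main__":
    main()
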