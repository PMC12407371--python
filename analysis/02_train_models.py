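#!/usr/bin/env python
"""Train the per-cultivar CVAE master models on the synthetic libraries.

Reads the libraries written by 01_build_libraries.py, trains the two
slave models (voltage and RWC) per cultivar, saves the weights under
scratch/models/ and a compact loss summary (first/last reconstruction
loss in physical units, mirroring how training convergence is usually
reported) to results/training_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from leafplp import calibration, cvae


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--epochs", type=int, default=2000)
    ap.add_argument("--libraries", type=Path, default=Path("results/libraries"))
    ap.add_argument("--models", type=Path, default=Path("scratch/models"))
    ap.add_argument("--out", type=Path, default=Path("results/training_summary.csv"))
    args = ap.parse_args()

    rows = []
    args.models.mkdir(parents=True, exist_ok=True)
    for name in ("honey", "japanese", "orange"):
        lib = calibration.read_library(args.libraries / name / "train")
        gen, traces = cvae.train(
            lib, cvae.CVAEConfig(epochs=args.epochs, seed=args.seed + 1)
        )
        cvae.save_generator(gen, args.models / f"{name}.json")
        for slave, trace in traces.items():
            unit = "mV^2" if slave == "voltage" else "%^2"
            rows.append(
                {
                    "cultivar": name,
                    "slave": slave,
                    "epochs": len(trace),
                    "recon_start": round(trace.recon_denorm[0], 3),
                    "recon_end": round(trace.recon_denorm[-1], 3),
                    "unit": unit,
                    "kl_end": round(trace.kl[-1], 6),
                }
            )
            print(
                f"{name}/{slave}: reconstruction {trace.recon_denorm[0]:.2f} -> "
                f"{trace.recon_denorm[-1]:.2f} {unit} over {len(trace)} epochs"
            )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"models in {args.models}, summary in {args.out}")


if __name__ == "__main__":
    main()
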