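#!/usr/bin/env python
"""Build the synthetic three-cultivar training and hold-out libraries.

Generates the study-design libraries (100 Honey, 50 Japanese, 50 Orange
leaves; 10-point V_TRx-RWC curve + 5 morphometric features per leaf)
plus the 10/5/5 hold-out sets, writes them as CSV under
results/libraries/, and prints the per-cultivar feature spreads
((max-min)/min, in %) so they can be eyeballed against the design's
target percentages.
"""

import argparse
from pathlib import Path

import numpy as np

from leafplp import calibration, synthetic

TEST_LEAVES = {"honey": 10, "japanese": 5, "orange": 5}
FEATURES = ["area", "perimeter", "A/P", "thickness", "skewness"]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/libraries"))
    args = ap.parse_args()

    total = 0
    for name in ("honey", "japanese", "orange"):
        spec = synthetic.get_spec(name)
        train = synthetic.generate_library(spec, seed=args.seed)
        hold = synthetic.generate_library(
            spec, n=TEST_LEAVES[name], seed=args.seed + 10007
        )
        calibration.write_library(train, args.out / name / "train")
        calibration.write_library(hold, args.out / name / "holdout")
        total += train.n_leaves

        spreads = [
            100.0 * (col.max() - col.min()) / col.min() for col in train.features.T
        ]
        vmax = train.v_matrix.max(axis=1)
        print(f"{name}: {train.n_leaves} train + {hold.n_leaves} hold-out leaves")
        print(
            "  feature spreads (%): "
            + ", ".join(f"{f} {s:.0f}" for f, s in zip(FEATURES, spreads))
        )
        print(
            f"  per-leaf max V_TRx: {vmax.min():.0f}-{vmax.max():.0f} mV"
            + (
                f" (bimodal: {np.median(vmax[vmax < 450]):.0f} vs "
                f"{np.median(vmax[vmax >= 450]):.0f} mV)"
                if name == "honey"
                else ""
            )
        )
    print(f"total training leaves: {total}")


if __name__ == "__main__":
    main()
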