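#!/usr/bin/env python
"""Hold-out evaluation: best-of-10/5/5 RMSEs for the three cultivars.

Loads the trained models and hold-out libraries, predicts each unseen
leaf's characteristic curve from its features alone, and reports
per-leaf and best/mean V_TRx and RWC RMSEs to
results/holdout_eval.csv / .json.  "Best" is the minimum over the
evaluated leaves (an optimistic summary, labeled as such).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from leafplp import calibration, cvae, transfer

TEST_LEAVES = {"honey": 10, "japanese": 5, "orange": 5}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--libraries", type=Path, default=Path("results/libraries"))
    ap.add_argument("--models", type=Path, default=Path("scratch/models"))
    ap.add_argument("--out", type=Path, default=Path("results/holdout_eval"))
    args = ap.parse_args()

    per_leaf, summary = [], {}
    for name, k in TEST_LEAVES.items():
        gen = cvae.load_generator(args.models / f"{name}.json")
        hold = calibration.read_library(args.libraries / name / "holdout")
        report = transfer.evaluate_holdout(gen, hold, best_of=k)
        df = report.per_leaf.assign(cultivar=name)
        per_leaf.append(df)
        summary[name] = report.to_dict()
        print(
            f"{name} (best of {k}): V_TRx RMSE {report.best_v_rmse:.2f} mV "
            f"(mean {report.mean_v_rmse:.2f}), RWC RMSE {report.best_rwc_rmse:.2f}% "
            f"(mean {report.mean_rwc_rmse:.2f}%)"
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(per_leaf).to_csv(args.out.with_suffix(".csv"), index=False)
    args.out.with_suffix(".json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {args.out.with_suffix('.csv')} and {args.out.with_suffix('.json')}")


if __name__ == "__main__":
    main()
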