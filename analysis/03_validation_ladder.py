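#!/usr/bin/env python
"""Externally validate the development model in the validation sample.

Runs the three-stage ladder — standard (model unchanged), adjusted
(intercept recalibrated so mean predicted risk equals observed prevalence),
refitted (coefficients re-estimated by penalized maximum likelihood) — and
writes the stage-comparison table, full-precision reports, and
calibration/ROC curve data.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import depval as dv
from depval.errors import DepvalError
from depval.metrics import flexible_calibration_curve, roc_curve_points
from depval.pmle import RiskModel


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--bootstrap", type=int, default=2000)
    args = ap.parse_args()

    model = RiskModel.from_json(args.out / "model.json")
    val = pd.read_csv(args.out / "cohorts" / "validation_analysis.csv")
    y = val["y"].to_numpy(dtype=float)

    stages = dv.run_validation_suite(model, val, B=args.bootstrap, seed=args.seed)
    table = dv.stage_table(stages)
    table.to_csv(args.out / "table1.csv")
    (args.out / "reports").mkdir(exist_ok=True)
    (args.out / "curves").mkdir(exist_ok=True)
    for st in stages:
        (args.out / "reports" / f"{st.label}.json").write_text(
            json.dumps(st.report.to_dict(), indent=2, sort_keys=True)
        )
        roc_curve_points(st.predictions.p, y).to_csv(
            args.out / "curves" / f"roc_{st.label}.csv", index=False
        )
        try:
            flexible_calibration_curve(st.predictions.p, y).to_frame().to_csv(
                args.out / "curves" / f"calibration_{st.label}.csv", index=False
            )
        except DepvalError as exc:
            print(f"calibration curve skipped for {st.label}: {exc}")

    print(f"validation sample: n={len(val)}, prevalence {100 * y.mean():.1f}%")
    print("\nstage comparison (2-decimal rendering):")
    print(table.to_string())
    std, adj = stages[0].report, stages[1].report
    print(f"\nIntercept recalibration moved calibration-in-the-large from "
          f"{std.citl:.2f} to {adj.citl:.2f} and the Brier score from "
          f"{std.brier:.2f} to {adj.brier:.2f}; the AUC ({std.auc:.2f}) is "
          f"unchanged by construction.")


if __name__ == "__main__":
    main()
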