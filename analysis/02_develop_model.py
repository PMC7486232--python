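#!/usr/bin/env python
"""Develop the penalized risk model in the development analysis sample.

Selects the ridge penalty on a grid by the modified AIC (likelihood-ratio
statistic minus twice the effective degrees of freedom), fits the model, and
writes it to JSON together with the penalty profile.
"""

import argparse
from pathlib import Path

import pandas as pd

import depval as dv
from depval.pmle import penalty_profile

GRID = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    sample = pd.read_csv(args.out / "cohorts" / "development_analysis.csv")
    X = sample[list(dv.DEFAULT_PREDICTOR_FREQS)]
    y = sample["y"].to_numpy(dtype=float)

    prof = penalty_profile(X, y, GRID)
    prof.to_csv(args.out / "penalty_profile.csv", index=False)
    lam = dv.choose_penalty(X, y, GRID)
    model = dv.fit_pmle(X, y, lam, provenance="development fit")
    model.to_json(args.out / "model.json")

    print(f"selected lambda = {lam:g} (modified AIC over grid {GRID})")
    print(prof.round(3).to_string(index=False))
    print("\ncoefficients (log-odds):")
    for name in model.predictor_names:
        print(f"  {name:18s} {model.coefficients[name]:+.3f}")
    print(f"  intercept          {model.intercept:+.3f}")


if __name__ == "__main__":
    main()
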