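#!/usr/bin/env python
"""Idealised sampling: with clean data all three estimators work well.

Draws one detection-filtered occurrence sample of m=100 from the virtual
species' niche, fits the classical, MCD and MVE location/scatter
estimates (k=0.55), and scores each by the correlation between the true
growth rate lambda_F and the modelled niche probability at the sampled
points.  Writes the per-method correlations and a niche-probability
surface over environment space for the classical fit.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mahaniche import (
    EstimatorConfig,
    NicheParams,
    estimate_mcd,
    estimate_mve,
    estimate_sample,
    grid_frame,
    performance_correlation,
    sample_idealised,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--m", type=int, default=100)
    args = ap.parse_args()

    params = NicheParams()
    sample = sample_idealised(params, args.m, seed=args.seed)
    print(f"Idealised sample: m={sample.m}, "
          f"mean environment = ({sample.X[:, 0].mean():.2f} degC, "
          f"{sample.X[:, 1].mean():.0f} mm) vs optimum (7.5 degC, 1800 mm)")

    fits = {
        "sample": estimate_sample(sample.X),
        "mcd": estimate_mcd(sample.X, EstimatorConfig(k=0.55, seed=args.seed)),
        "mve": estimate_mve(sample.X, EstimatorConfig(k=0.55, seed=args.seed)),
    }
    rows = []
    for name, ls in fits.items():
        r = performance_correlation(params, sample, ls)
        rows.append({"method": name, "k": 0.55 if name != "sample" else np.nan,
                     "correlation": r})
        print(f"  {name:<7s} r(lambda_F, P(chi2_2 > D^2)) = {r:.4f}")
    print("All three methods track the true niche closely on clean data.")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "01_idealised_correlations.csv",
                              index=False)
    surface = grid_frame(fits["sample"],
                         np.linspace(2.0, 13.0, 23),
                         np.linspace(200.0, 4200.0, 21))
    surface.to_csv(RESULTS / "01_niche_probability_surface.csv", index=False)
    print(f"Wrote correlations and a {23 * 21}-cell probability surface "
          f"to {RESULTS}/")


if __name__ == "__main__":
    main()
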