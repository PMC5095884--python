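#!/usr/bin/env python
"""Step 4 — caliper proportionality constant and stroma fraction.

Freezes the individual trajectories from step 3, converts them to cm^3 with
the cells-to-light ratio and the 1e9 cells = 1 cm^3 rule, and fits lambda —
the caliper-to-cell-mass proportionality constant — as a lognormal
population parameter on the caliper observations.  The excess of lambda
over 1 is read as the stromal share of the tumor volume; the typical-animal
dynamics table (P, N, V on a dense grid) is written alongside.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lumigrowth import (
    LongitudinalDataset,
    ModelParameters,
    SaemSettings,
    fit_lambda,
    saem_fit,
    simulate_typical,
    stroma_fraction,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
P0_SIGNAL = 1.5e5 * 88.4


def main(seed: int = 1) -> None:
    data = LongitudinalDataset.from_csv(RESULTS / "cohort.csv")
    stage1 = saem_fit(data, P0_SIGNAL, settings=SaemSettings(seed=seed),
                      compute_se=False)
    stage2 = fit_lambda(stage1, data, p0_signal=P0_SIGNAL)
    lam = stage2.estimates.theta_mu["lam"]
    stroma = stroma_fraction(lam)

    typ = ModelParameters(
        a=stage1.estimates.theta_mu["a"],
        K=stage1.estimates.theta_mu["K"],
        P0=P0_SIGNAL,
        lam=lam,
    )
    table = simulate_typical(typ, np.linspace(0, 43, 173))
    table.to_csv(RESULTS / "typical_dynamics.csv", index=False)
    v43 = float(table["V_caliper_cm3"].iloc[-1])

    with open(RESULTS / "lambda_stroma.json", "w") as fh:
        json.dump(
            {"lambda": lam,
             "lambda_cv_percent": stage2.cv_percent["lam"],
             "lambda_rse_percent": stage2.rse_percent.get("lam"),
             "stroma_percent": stroma,
             "day43_caliper_volume_cm3": v43,
             "generating_lambda": 2.25,
             "seed": seed},
            fh, indent=2,
        )
    print(f"lambda: {lam:.3f} (CV {stage2.cv_percent['lam']:.1f}%, "
          f"RSE {stage2.rse_percent.get('lam', float('nan')):.2f}%)  "
          f"[generating value 2.25]")
    print(f"stroma fraction: {stroma:.1f}% of total volume")
    print(f"typical caliper volume at day 43: {v43:.2f} cm^3")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
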