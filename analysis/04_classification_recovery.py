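#!/usr/bin/env python
"""Parameter recovery: does the pipeline find signal iff the generator put it in?

Three experiments on synthetic cohorts:

* null calibration — a zero-effect cohort must yield chance-level BAC;
* strong-effect recovery — a d=2 cohort must yield high fused BAC;
* dose response — mean BAC over seeds must increase with the effect size.

Writes results/recovery.csv.
"""

from pathlib import Path

import pandas as pd

from avphenotype.experiments import (
    effect_size_bac_curve,
    null_calibration_bac,
    strong_effect_bac,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    null_bac, band = null_calibration_bac(seed=1)
    rows.append({"experiment": "null (effect 0, n=60)", "bac": round(null_bac, 3),
                 "note": f"95% chance band [{band[0]:.3f}, {band[1]:.3f}]"})
    strong = strong_effect_bac(seed=1)
    rows.append({"experiment": "strong effect (d=2, n=60)", "bac": round(strong, 3),
                 "note": "fused over LIWC + Diction"})
    curve = effect_size_bac_curve()
    for eff, bac in curve.items():
        rows.append({"experiment": f"dose response d={eff}", "bac": round(bac, 3),
                     "note": "mean over 10 seeds, logistic-only ensemble"})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "recovery.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
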