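#!/usr/bin/env python
"""Targeted carotenoid quantification demo: calibration, LOQ, serving math.

Fits a six-point external calibration, quantifies simulated detector
responses for diluted extracts, converts dry-weight concentrations to a
fresh-weight basis at 92% water, and computes the peel vs pulp lutein
contribution to a 100 g serving.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tomarker.quant import BELOW_LOQ, fit_calibration, part_contribution, quantify

OUT = Path("results/analysis")
SEED = 20260918


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    concentrations = [1.56, 3.13, 6.25, 12.5, 25.0, 50.0, 100.0]
    slope_true, noise_sd = 120.0, 40.0
    rows = []
    for analyte, dilution in [("lutein", 1), ("lycopene", 20), ("phytoene", 20),
                              ("neoxanthin", 1)]:
        points = [(c, slope_true * c + rng.normal(0, noise_sd)) for c in concentrations]
        curve = fit_calibration(analyte, points, min_points=6)
        # plausible dw levels: trace for neoxanthin, high for lycopene/phytoene
        true_dw = {"lutein": 9.0, "lycopene": 500.0, "phytoene": 600.0,
                   "neoxanthin": 0.9}[analyte]
        response = (true_dw / dilution) * curve.slope + curve.intercept
        q = quantify(response, curve, dilution_factor=dilution, water_fraction=0.92)
        rows.append({
            "analyte": analyte,
            "r_squared": round(curve.r_squared, 5),
            "loq_ug_g_dw": curve.loq,
            "dw_ug_g": q.concentration_dw if q.concentration_dw is not BELOW_LOQ else "<LOQ",
            "fw_mg_kg": q.concentration_fw if q.concentration_fw is not BELOW_LOQ else "<LOQ",
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "carotenoid_quant.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    pulp = part_contribution(0.55, 0.93, 100.0)   # mg/kg fw pulp, 93% of mass
    peel = part_contribution(1.6, 0.05, 100.0)    # mg/kg fw peel, 5% of mass
    print(f"lutein per 100 g serving: pulp {pulp:.3f} mg vs peel {peel:.3f} mg")
    print("  (peel is richer per gram but contributes little mass, so "
          "peeling alone cannot explain lower lutein in processed fruit)")


if __name__ == "__main__":
    main()
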