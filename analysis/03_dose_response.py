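#!/usr/bin/env python
"""Betaine dose-response kinetics: Imax, K0.5, Hill exponent, and transport
efficiency Imax/K0.5 with delta-method uncertainty.

Writes results/dose_response_fit.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, RESULTS, dataset_dir

from gatkin.io import read_dose_csv, read_report
from gatkin.steady_kinetics import fit_dose_response


def main(seed: int = DEFAULT_SEED) -> None:
    data = dataset_dir(seed)
    table = read_dose_csv(data / "dose_response.csv")
    truth = read_report(data / "ground_truth.json")["payload"]["dose_response"]
    fit = fit_dose_response(table)

    out = pd.DataFrame([{
        "Imax_nA": fit.Imax_nA, "Imax_se": fit.se.get("Imax"),
        "K05_mM": fit.K_half, "K05_se": fit.se.get("K_half"),
        "p": fit.p, "p_se": fit.se.get("p"),
        "efficiency_nA_per_mM": fit.efficiency, "efficiency_se": fit.efficiency_se,
        "true_Imax_nA": truth["Imax_nA"], "true_K05_mM": truth["K_half_mM"],
    }])
    out.to_csv(RESULTS / "dose_response_fit.csv", index=False)
    print(f"Imax  = {fit.Imax_nA:8.2f} +- {fit.se.get('Imax', float('nan')):.2f} nA "
          f"(truth {truth['Imax_nA']})")
    print(f"K0.5  = {fit.K_half:8.2f} +- {fit.se.get('K_half', float('nan')):.2f} mM "
          f"(truth {truth['K_half_mM']})")
    print(f"p     = {fit.p:8.2f}")
    print(f"Imax/K0.5 = {fit.efficiency:6.2f} +- {fit.efficiency_se:.2f} nA/mM")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
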