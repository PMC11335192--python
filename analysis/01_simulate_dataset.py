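#!/usr/bin/env python
"""Generate the seeded synthetic dataset all later steps analyze.

Writes (under scratch/run-<seed>/): per-condition voltage-step sweep CSVs
(blocker, ND98, four betaine concentrations), the condition manifest, the
7-point betaine dose-response table, the 84-condition competition long table,
the 5-dose efflux assay, and the ground-truth JSON the recovery steps compare
against.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, dataset_dir

from gatkin.io import read_report


def main(seed: int = DEFAULT_SEED) -> None:
    out = dataset_dir(seed)
    truth = read_report(out / "ground_truth.json")["payload"]
    print(f"dataset: {out}")
    print(f"  files: {len(list(out.glob('sweeps_*.csv')))} sweep sets, "
          "dose_response.csv, competition.csv, efflux.csv")
    cm = truth["charge_movement"]
    print(f"  ground truth: Qmax {cm['Qmax_nC']} nC, V_half {cm['V_half_mV']} mV, "
          f"sigma {cm['sigma_mV']:.2f} mV, k0 {cm['k0_per_s']}/s")
    print(f"  noise: {truth['noise']['sd_current_nA']:.2f} nA additive on traces, "
          f"{100 * truth['noise']['sd_rel']:.0f}% multiplicative on tables")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
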