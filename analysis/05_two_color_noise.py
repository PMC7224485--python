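#!/usr/bin/env python
"""Intrinsic/extrinsic decomposition of the two-colour snapshots.

Reads results/data/snapshots.csv (from 01_generate_data.py) and prints the
dual-reporter noise decomposition: eta_int from the channel differences
within cells, eta_ext from the covariance across cells, with
eta_tot^2 = eta_int^2 + eta_ext^2.  Writes results/noise_decomposition.csv.

In the generated data the extrinsic component dominates (0.3 vs 0.1),
mirroring the situation where shared environmental fluctuations, not
molecule-level stochasticity, drive most of the cell-to-cell variability.
"""

import sys
from pathlib import Path

import pandas as pd

import fpmat as fm

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    snaps = pd.read_csv(ROOT / "data" / "snapshots.csv")
    d = fm.elowitz_decompose(snaps["c1"], snaps["c2"])
    row = pd.DataFrame([{
        "n_cells": d.n_cells, "eta_int": d.eta_int, "eta_ext": d.eta_ext,
        "eta_tot": d.eta_tot, "ext_negative": d.ext_negative,
    }])
    row.to_csv(ROOT / "noise_decomposition.csv", index=False)
    print(row.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    if d.eta_ext > d.eta_int:
        print("=> extrinsic (shared-environment) noise dominates the "
              "intrinsic component")
    return 0


if __name__ == "__main__":
    sys.exit(main())
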