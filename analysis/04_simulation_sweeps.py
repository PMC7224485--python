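#!/usr/bin/env python
"""Stochastic-simulation sweeps of maturation under a fluctuating rate.

Each condition simulates 100 cells x 2,000 molecules; each cell carries its
own white-noise rate-constant series (Gaussian amplitudes, grid lag 0.2 min)
and the Gillespie steps use the dwell-window time-averaged rate.  Writes
tidy tables and a figure under results/simulation/:

  sweep_rate.csv         - CV of half-maturation time vs mean maturation
                           time (10-140 min), sigma_rel = 0.5
  sweep_sigma.csv        - CV vs noise amplitude (0-1 x mean rate) at 30 min
  sweep_copy_number.csv  - CV vs molecules per cell (20, 200, 2000)

The rate sweep is the model's core prediction: slower reactions average the
environmental fluctuations over longer windows, so their noise falls toward
the molecule-level (intrinsic) floor.  The copy-number sweep is reported
descriptively.
"""

import sys
from pathlib import Path

import fpmat as fm
from fpmat.pipeline import SimFigureConfig, run_simulation_figures
from fpmat.simulate import half_time_floor_stats

OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"
SEED = 2026


def main() -> int:
    cfg = SimFigureConfig(seed=SEED,
                          base=fm.SimConfig(mean_mat_time=20.0, sigma_rel=0.5))
    report = run_simulation_figures(cfg, outdir=OUT)
    for name, df in report["tables"].items():
        print(f"--- {name} sweep ---")
        print(df.drop(columns=["axis"]).to_string(
            index=False, float_format=lambda v: f"{v:.4f}"))
    _, floor = half_time_floor_stats(cfg.base.n_molecules, 1.0)
    print(f"\nintrinsic (molecule-level) CV floor at n=2000: {floor:.4f}")
    rate = report["tables"]["rate"]
    if rate["cv"].is_monotonic_decreasing:
        print("=> rate sweep: CV decreases monotonically with maturation time")
    return 0


if __name__ == "__main__":
    sys.exit(main())
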