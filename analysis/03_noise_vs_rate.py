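#!/usr/bin/env python
"""Noise level versus maturation rate across the reporter panel.

Reads results/fits.csv (from 02_fit_maturation.py); writes
  results/noise_summary.csv  - per condition: n kept, mean maturation time,
                               CV with bias-corrected bootstrap 95% CI
  results/noise_vs_rate.png  - the noise-vs-rate scatter

The headline statistic is the Pearson correlation between the per-condition
mean maturation time and its CV: a negative correlation means slow-maturing
reporters are less heterogeneous, the signature of time-averaged filtering of
shared environmental fluctuations.
"""

import sys
from pathlib import Path

import pandas as pd

import fpmat as fm
from fpmat.pipeline import _plot_noise_vs_rate, summarize_panel_fits

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> int:
    fits = pd.read_csv(ROOT / "fits.csv")
    by_condition = {name: grp for name, grp in fits.groupby("condition")}
    summary = summarize_panel_fits(by_condition, seed=SEED)
    summary.to_csv(ROOT / "noise_summary.csv", index=False)

    corr = fm.pearson_test(summary["mean_mat_time"], summary["cv"])
    _plot_noise_vs_rate(summary, corr, ROOT / "noise_vs_rate.png")
    print(summary.to_string(index=False,
                            float_format=lambda v: f"{v:.3f}"))
    print(f"\nnoise vs maturation time: Pearson r = {corr.r:.2f}, "
          f"t = {corr.t:.2f}, df = {corr.df}, p = {corr.p:.2g}")
    if corr.r < 0 and corr.p < 0.05:
        print("=> slower-maturing reporters carry less cell-to-cell noise "
              "(rate-dependent filtering recovered)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
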