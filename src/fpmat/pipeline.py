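"""End-to-end recipes: synthetic panel -> fits -> noise-vs-rate statistics,
and the stochastic-simulation sweep bundle.

Each recipe is a plain function returning a report dict; when given an output
directory it also writes tidy CSV tables, a figure, and a JSON run manifest.
All randomness flows from the config seed, so identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import FitOptions, fit_trace_set
from .noise import bootstrap_bc_ci, cv, pearson_test
from .simulate import SimConfig, half_time_floor_stats, sweep
from .synthetic import default_panel_configs, generate_fp_panel

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryConfig",
    "SimFigureConfig",
    "run_recovery_experiment",
    "run_simulation_figures",
    "summarize_panel_fits",
    "rate_dependent_cv",
]


def rate_dependent_cv(mat_time: float, cv_at_10: float = 0.45,
                      ref_time: float = 10.0) -> float:
    """Maturation-time CV following the time-averaging square-root law.

    Environmental fluctuations averaged over a window proportional to the
    reaction timescale give cell-to-cell noise that scales as
    1/sqrt(maturation time); anchored at ``cv_at_10`` for a 10-min reporter,
    which spans roughly 0.45 down to 0.12 over the 10-140 min range.
    """
    return cv_at_10 * (ref_time / mat_time) ** 0.5


@dataclass(frozen=True)
class RecoveryConfig:
    """Settings for the panel-recovery recipe (a synthetic analogue of the
    14-reporter noise-vs-rate experiment)."""

    seed: int = 0
    n_conditions: int = 14
    mat_time_range: tuple[float, float] = (10.0, 140.0)
    n_cells: int | None = None  # None -> per-condition draw from [16, 130]
    rate_dependent_noise: bool = True  # cv_mat_time ~ 1/sqrt(mat_time)
    flat_cv_mat_time: float = 0.2  # used when rate_dependent_noise is False
    meas_noise_cv: float = 0.02
    scaling_ratio_R: float = 0.5
    alpha: float = 0.03
    r2_threshold: float = 0.98
    bootstrap_B: int = 2000


def _manifest(config, outdir: Path) -> None:
    payload = {"config": asdict(config), "fpmat_version": __version__,
               "python": platform.python_version(),
               "numpy": np.__version__, "pandas": pd.__version__}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2))


def summarize_panel_fits(fits_by_condition: dict[str, pd.DataFrame],
                         bootstrap_B: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-condition summary from fit tables: kept-cell count, mean maturation
    time, CV with a bias-corrected bootstrap CI.

    Cells failing QC or flagged as MAD outliers are excluded from the
    summary statistics (they stay visible in the per-cell tables).
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for (name, fits), child in zip(fits_by_condition.items(),
                                   ss.spawn(len(fits_by_condition))):
        kept = fits[fits["qc_pass"] & ~fits["outlier"]]["mat_time_min"].to_numpy()
        the_cv = cv(kept)
        lo, hi = bootstrap_bc_ci(kept, cv, B=bootstrap_B,
                                 rng=np.random.default_rng(child))
        rows.append({"condition": name, "n_cells": int(len(fits)),
                     "n_kept": int(kept.size),
                     "mean_mat_time": float(kept.mean()),
                     "median_mat_time": float(np.median(kept)),
                     "cv": the_cv, "cv_lo": lo, "cv_hi": hi})
    return pd.DataFrame(rows)


def run_recovery_experiment(config: RecoveryConfig | None = None,
                            outdir: str | Path | None = None) -> dict:
    """Generate a reporter panel, fit every cell, and test noise vs rate.

    Returns a report with the per-cell fits, the per-condition summary, and
    the Pearson correlation test of CV against mean maturation time.
    """
    cfg = config or RecoveryConfig()
    cv_rule = rate_dependent_cv if cfg.rate_dependent_noise else cfg.flat_cv_mat_time
    panel_cfgs = default_panel_configs(
        seed=cfg.seed, n_conditions=cfg.n_conditions,
        mat_time_range=cfg.mat_time_range, n_cells=cfg.n_cells,
        cv_mat_time=cv_rule, meas_noise_cv=cfg.meas_noise_cv,
        scaling_ratio_R=cfg.scaling_ratio_R, alpha=cfg.alpha)
    panel = generate_fp_panel(panel_cfgs)
    opts = FitOptions(r2_threshold=cfg.r2_threshold)
    fits = {name: fit_trace_set(traces, R=cfg.scaling_ratio_R, alpha=cfg.alpha,
                                options=opts)
            for name, traces in panel.items()}
    for name, df in fits.items():
        logger.info("%s: %d cells, %d qc-pass, %d outliers", name, len(df),
                    int(df["qc_pass"].sum()), int(df["outlier"].sum()))
    summary = summarize_panel_fits(fits, bootstrap_B=cfg.bootstrap_B,
                                   seed=cfg.seed)
    corr = pearson_test(summary["mean_mat_time"], summary["cv"])
    report = {"fits": fits, "summary": summary, "correlation": corr,
              "panel_configs": panel_cfgs}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.concat([df.assign(condition=name) for name, df in fits.items()],
                  ignore_index=True).to_csv(outdir / "fits.csv", index=False)
        summary.to_csv(outdir / "noise_summary.csv", index=False)
        _plot_noise_vs_rate(summary, corr, outdir / "noise_vs_rate.png")
        _manifest(cfg, outdir)
    return report


@dataclass(frozen=True)
class SimFigureConfig:
    """Settings for the simulation sweep bundle (rate, noise amplitude, and
    copy-number axes; 100 cells x 2,000 molecules per condition)."""

    seed: int = 0
    base: SimConfig = field(default_factory=SimConfig)
    mat_times: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 140.0)
    sigma_rels: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)
    n_molecules_values: tuple[int, ...] = (20, 200, 2000)
    sigma_sweep_mat_time: float = 30.0


def run_simulation_figures(config: SimFigureConfig | None = None,
                           outdir: str | Path | None = None) -> dict:
    """Execute the three sweeps and collect their tidy tables.

    ``rate``: CV of half-maturation time across mean maturation times (the
    time-averaging prediction: slower reactions are quieter).  ``sigma``:
    CV across environmental-noise amplitudes at a fixed 30-min reporter.
    ``copy_number``: CV across molecules-per-cell; the direction of this
    trend is recorded, not asserted.
    """
    cfg = config or SimFigureConfig()
    from dataclasses import replace
    base = replace(cfg.base, seed=cfg.seed)
    tables = {
        "rate": sweep(base, "mat_time", cfg.mat_times),
        "sigma": sweep(replace(base, mean_mat_time=cfg.sigma_sweep_mat_time,
                               lag=None, horizon=None),
                       "sigma", cfg.sigma_rels),
        "copy_number": sweep(base, "n_molecules", cfg.n_molecules_values),
    }
    _, floor_cv = half_time_floor_stats(base.n_molecules, 1.0)
    report = {"tables": tables, "intrinsic_floor_cv": floor_cv}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"sweep_{name}.csv", index=False)
        _plot_sweeps(tables, floor_cv, outdir / "simulation_sweeps.png")
        _manifest(cfg, outdir)
    return report


# --------------------------------------------------------------------------
# plotting helpers (matplotlib, Agg-safe)


def _plot_noise_vs_rate(summary: pd.DataFrame, corr, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    yerr = np.vstack([summary["cv"] - summary["cv_lo"],
                      summary["cv_hi"] - summary["cv"]])
    ax.errorbar(summary["mean_mat_time"], summary["cv"], yerr=np.abs(yerr),
                fmt="o", capsize=3)
    ax.set_xlabel("mean maturation time (min)")
    ax.set_ylabel("noise level (CV of maturation time)")
    ax.set_title(f"r = {corr.r:.2f}, t = {corr.t:.2f}, df = {corr.df}, "
                 f"p = {corr.p:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweeps(tables: dict[str, pd.DataFrame], floor_cv: float,
                 path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    labels = {"rate": "mean maturation time (min)",
              "sigma": "sigma / mean rate",
              "copy_number": "molecules per cell"}
    for ax, (name, df) in zip(axes, tables.items()):
        yerr = np.abs(np.vstack([df["cv"] - df["cv_lo"], df["cv_hi"] - df["cv"]]))
        ax.errorbar(df["value"], df["cv"], yerr=yerr, fmt="o-", capsize=3)
        if name in ("rate", "copy_number"):
            ax.set_xscale("log")
        if name == "sigma":
            ax.axhline(floor_cv, ls="--", color="grey", lw=1,
                       label="intrinsic floor")
            ax.legend(frameon=False)
        ax.set_xlabel(labels[name])
        ax.set_ylabel("CV of half-maturation time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
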