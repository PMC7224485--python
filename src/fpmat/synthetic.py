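"""Synthetic single-cell data generators.

Emulates the three kinds of input the analysis consumes:

* induction time-lapse trajectories (two channels sampled every 6 min for 6 h
  after inducer addition) under the analytic production/maturation kinetics,
  with lognormal cell-to-cell variability in the production rate ``k`` and the
  maturation time, multiplicative lognormal measurement noise, and optional
  background offsets;
* steady-state scaling-ratio experiments (a background phase before induced
  protein appears, then a post-shutoff steady-state phase) used to calibrate
  the channel scaling ratio ``R``;
* two-colour snapshots with controlled intrinsic/extrinsic variance structure
  for the dual-reporter noise decomposition.

All randomness flows from integer seeds; per-cell substreams are derived by
cell counter, so changing ``n_cells`` never reshuffles earlier cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import LN2, KineticParams, analytic_curves

__all__ = [
    "TraceGenConfig",
    "CellTrace",
    "TwoColorConfig",
    "ScalingConfig",
    "generate_trace_set",
    "generate_fp_panel",
    "default_panel_configs",
    "generate_scaling_experiment",
    "generate_two_color_snapshots",
    "traces_to_frame",
    "frame_to_traces",
    "truth_to_frame",
]


@dataclass(frozen=True)
class CellTrace:
    """One cell's time-stamped two-channel fluorescence trajectory."""

    cell_id: object
    times: np.ndarray  # minutes since induction (time zero = inducer addition)
    fc: np.ndarray  # constitutive-channel nuclear fluorescence (a.u.)
    fi: np.ndarray  # inducible-channel nuclear fluorescence (a.u.)
    true_params: KineticParams | None = None  # only for synthetic data

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) != len(self.fc) or len(t) != len(self.fi):
            raise ValueError("times, fc, fi must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.fc)) and np.all(np.isfinite(self.fi))):
            raise ValueError("fc and fi must be finite")


def _check_positive(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")


def _check_nonneg(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not v >= 0:
            raise ValueError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class TraceGenConfig:
    """Configuration of one synthetic induction-trajectory condition.

    ``mean_k`` is the composite production rate k1*k2 (a.u. min^-2);
    ``mean_mat_time`` sets the mean maturation rate via k3 = ln2 / mat_time.
    Cell-to-cell variability of both is lognormal with the given CVs.
    Measurement noise is an independent multiplicative lognormal factor per
    observation (default 2% CV); backgrounds are additive offsets applied
    before the noise factor.
    """

    n_cells: int = 50
    frame_interval: float = 6.0  # minutes; imaging cadence
    duration: float = 360.0  # minutes post-induction
    mean_k: float = 5.0  # a.u. min^-2
    cv_k: float = 0.3
    mean_mat_time: float = 30.0  # minutes
    cv_mat_time: float = 0.2
    alpha: float = 0.03  # min^-1, mRNA turnover
    scaling_ratio_R: float = 0.5
    meas_noise_cv: float = 0.02
    bg_fc: float = 0.0
    bg_fi: float = 0.0
    n_preinduction_frames: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive(self, ("n_cells", "frame_interval", "duration", "mean_k",
                               "mean_mat_time", "alpha", "scaling_ratio_R"))
        _check_nonneg(self, ("cv_k", "cv_mat_time", "meas_noise_cv",
                             "bg_fc", "bg_fi", "n_preinduction_frames"))
        if not self.frame_interval < self.duration:
            raise ValueError("frame_interval must be smaller than duration")


@dataclass(frozen=True)
class TwoColorConfig:
    """Two-colour snapshot generator with controlled noise structure.

    Each cell's channels are c_j = mean_level * G * I_j with a shared
    lognormal factor G (CV ``eta_ext``) and independent lognormal factors
    I_j (CV ``eta_int``), all unit mean.
    """

    n_cells: int = 245
    mean_level: float = 1000.0
    eta_int: float = 0.1
    eta_ext: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        _check_nonneg(self, ("eta_int", "eta_ext"))
        _check_positive(self, ("mean_level",))
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")


@dataclass(frozen=True)
class ScalingConfig:
    """Scaling-ratio experiment: background phase, then matured steady state.

    The background movie covers [0, 30) min at 3-min cadence (before induced
    protein is visible); the steady-state movie covers 2 h at 20-min cadence
    starting 7 h after transcription shutoff, when production has stopped and
    the whole pool has matured, so fi_ss - bg_fi = R * (fc_ss - bg_fc).
    """

    n_cells: int = 50
    scaling_ratio_R: float = 0.5
    mean_ss_level: float = 500.0  # steady-state constitutive increment (a.u.)
    cv_ss_level: float = 0.4  # cell-to-cell expression variability
    bg_fc: float = 50.0
    bg_fi: float = 20.0
    meas_noise_cv: float = 0.02
    bg_start: float = 0.0
    bg_frames: int = 10
    bg_interval: float = 3.0
    ss_start: float = 450.0  # minutes (7.5 h after time zero)
    ss_frames: int = 7
    ss_interval: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive(self, ("n_cells", "scaling_ratio_R", "bg_frames",
                               "bg_interval", "ss_frames", "ss_interval"))
        _check_nonneg(self, ("mean_ss_level", "cv_ss_level", "bg_fc", "bg_fi",
                             "meas_noise_cv"))
        bg_end = self.bg_start + self.bg_frames * self.bg_interval
        if self.ss_start < bg_end:
            raise ValueError("steady-state phase must start after the background phase")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def _lognormal_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    return float(mean * _lognormal_factors(rng, cv, size=()))


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    # counter-keyed substream: stable under n_cells changes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_trace_set(config: TraceGenConfig) -> list[CellTrace]:
    """Generate one condition's worth of induction trajectories."""
    n_pre = config.n_preinduction_frames
    times = (np.arange(-n_pre, int(round(config.duration / config.frame_interval)) + 1)
             * config.frame_interval)
    t_signal = np.clip(times, 0.0, None)
    traces = []
    for i in range(config.n_cells):
        rng = _cell_rng(config.seed, i)
        k = _lognormal_draw(rng, config.mean_k, config.cv_k)
        mat_time = _lognormal_draw(rng, config.mean_mat_time, config.cv_mat_time)
        params = KineticParams(k=k, k3=LN2 / mat_time, alpha=config.alpha,
                               R=config.scaling_ratio_R)
        curves = analytic_curves(params, t_signal)
        fc = curves.p_total / params.R + config.bg_fc
        fi = curves.fi + config.bg_fi
        fc = fc * _lognormal_factors(rng, config.meas_noise_cv, fc.shape)
        fi = fi * _lognormal_factors(rng, config.meas_noise_cv, fi.shape)
        traces.append(CellTrace(cell_id=i, times=times.astype(float), fc=fc,
                                fi=fi, true_params=params))
    return traces


def default_panel_configs(
    seed: int = 0,
    n_conditions: int = 14,
    mat_time_range: tuple[float, float] = (10.0, 140.0),
    n_cells: int | None = None,
    cv_mat_time=None,
    **overrides,
) -> dict[str, TraceGenConfig]:
    """Panel of conditions spanning the measured maturation-time range.

    Mean maturation times are log-spaced over ``mat_time_range`` (the range
    measured across common fluorescent proteins).  Per-condition cell counts
    default to a seeded draw from [16, 130], matching typical per-FP dataset
    sizes; ``cv_mat_time`` may be a scalar or a callable of the mean
    maturation time (used to build rate-dependent-noise panels).
    """
    if n_conditions < 2:
        raise ValueError("a panel needs >= 2 conditions")
    mat_times = np.geomspace(*mat_time_range, n_conditions)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xFF,)))
    configs: dict[str, TraceGenConfig] = {}
    for j, mt in enumerate(mat_times):
        n = n_cells if n_cells is not None else int(rng.integers(16, 131))
        kwargs = dict(overrides)
        if cv_mat_time is not None:
            kwargs["cv_mat_time"] = (cv_mat_time(mt) if callable(cv_mat_time)
                                     else float(cv_mat_time))
        configs[f"FP{j + 1:02d}"] = TraceGenConfig(
            n_cells=n, mean_mat_time=float(mt), seed=seed, **kwargs)
    return configs


def generate_fp_panel(
    configs: Mapping[str, TraceGenConfig],
) -> dict[str, list[CellTrace]]:
    """Generate one trace set per labelled condition.

    Each condition draws from its own substream keyed by (config seed,
    condition index), so identically configured conditions still produce
    independent cells.
    """
    if isinstance(configs, Mapping):
        pairs = list(configs.items())
    else:
        pairs = list(configs)
    names = [name for name, _ in pairs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate condition names")
    if len(names) < 2:
        raise ValueError("a panel needs >= 2 conditions")
    panel: dict[str, list[CellTrace]] = {}
    for idx, (name, cfg) in enumerate(pairs):
        child = int(np.random.SeedSequence(cfg.seed, spawn_key=(idx + 1,))
                    .generate_state(1)[0] & 0x7FFFFFFF)
        panel[name] = generate_trace_set(replace(cfg, seed=child))
    return panel


def generate_scaling_experiment(config: ScalingConfig) -> pd.DataFrame:
    """Tidy (cell_id, time_min, fc, fi, phase) table of a scaling experiment."""
    t_bg = config.bg_start + np.arange(config.bg_frames) * config.bg_interval
    t_ss = config.ss_start + np.arange(config.ss_frames) * config.ss_interval
    rows = []
    for i in range(config.n_cells):
        rng = _cell_rng(config.seed, i)
        level = _lognormal_draw(rng, config.mean_ss_level, config.cv_ss_level) \
            if config.mean_ss_level > 0 else 0.0
        for phase, tt, fc0, fi0 in (
            ("background", t_bg, config.bg_fc, config.bg_fi),
            ("steady_state", t_ss, config.bg_fc + level,
             config.bg_fi + config.scaling_ratio_R * level),
        ):
            fc = fc0 * _lognormal_factors(rng, config.meas_noise_cv, tt.shape)
            fi = fi0 * _lognormal_factors(rng, config.meas_noise_cv, tt.shape)
            rows.append(pd.DataFrame({
                "cell_id": i, "time_min": tt, "fc": fc, "fi": fi, "phase": phase,
            }))
    return pd.concat(rows, ignore_index=True)


def generate_two_color_snapshots(config: TwoColorConfig) -> pd.DataFrame:
    """Snapshot table (cell_id, c1, c2) with controlled noise components."""
    rng = np.random.default_rng(config.seed)
    g = _lognormal_factors(rng, config.eta_ext, config.n_cells)
    i1 = _lognormal_factors(rng, config.eta_int, config.n_cells)
    i2 = _lognormal_factors(rng, config.eta_int, config.n_cells)
    return pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "c1": config.mean_level * g * i1,
        "c2": config.mean_level * g * i2,
    })


def traces_to_frame(traces: Sequence[CellTrace],
                    condition: str | None = None) -> pd.DataFrame:
    """Tidy trajectory table `cell_id,time_min,fc,fi[,condition]`."""
    df = pd.concat(
        [pd.DataFrame({"cell_id": tr.cell_id, "time_min": tr.times,
                       "fc": tr.fc, "fi": tr.fi}) for tr in traces],
        ignore_index=True)
    if condition is not None:
        df["condition"] = condition
    return df


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    """Rebuild trace objects from a tidy `cell_id,time_min,fc,fi` table."""
    traces = []
    for cell_id, grp in df.sort_values("time_min").groupby("cell_id", sort=True):
        traces.append(CellTrace(
            cell_id=cell_id,
            times=grp["time_min"].to_numpy(dtype=float),
            fc=grp["fc"].to_numpy(dtype=float),
            fi=grp["fi"].to_numpy(dtype=float)))
    return traces


def truth_to_frame(traces: Sequence[CellTrace],
                   condition: str | None = None) -> pd.DataFrame:
    """Ground-truth sidecar `cell_id,k_true,k3_true,mat_time_true`."""
    rows = [(tr.cell_id, tr.true_params.k, tr.true_params.k3,
             tr.true_params.maturation_time)
            for tr in traces if tr.true_params is not None]
    df = pd.DataFrame(rows, columns=["cell_id", "k_true", "k3_true",
                                     "mat_time_true"])
    if condition is not None:
        df["condition"] = condition
    return df
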