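"""Noise statistics: CV, MAD outlier filtering, bias-corrected bootstrap,
dual-reporter intrinsic/extrinsic decomposition, Pearson correlation test."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "cv",
    "mad_outliers",
    "bootstrap_bc_ci",
    "NoiseDecomposition",
    "elowitz_decompose",
    "CorrelationTest",
    "pearson_test",
    "t_from_r",
    "nc_ratio",
]

MAD_SCALE = 1.4826  # consistency constant for the normal distribution


def cv(values, axis=None):
    """Coefficient of variation: sample SD (n-1 denominator) / mean.

    With ``axis`` given, computes along that axis without validation (used by
    vectorised bootstrap resampling); the scalar form validates its input.
    """
    x = np.asarray(values, dtype=float)
    if axis is not None:
        return x.std(axis=axis, ddof=1) / x.mean(axis=axis)
    if x.size < 2:
        raise ValueError("cv requires at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValueError(f"cv requires a positive mean, got {m}")
    return float(x.std(ddof=1) / m)


def mad_outliers(values, cutoff: float = 3.0) -> np.ndarray:
    """Flag outliers by robust z-score |x - median| / (1.4826 * MAD) > cutoff.

    MAD is the median absolute deviation from the median.  A zero MAD (more
    than half the values identical) yields no flags.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("mad_outliers requires at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        logger.warning("MAD is zero (n=%d); no outliers flagged", x.size)
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) / (MAD_SCALE * mad) > cutoff


def bootstrap_bc_ci(values, statistic, B: int = 2000, level: float = 0.95,
                    seed=None, rng=None) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap confidence interval.

    Resamples ``values`` with replacement ``B`` times; the bias-correction
    constant z0 is the normal quantile of the fraction of resampled statistics
    below the observed one (ties counted with half weight), and the interval
    endpoints are the bootstrap percentiles at Phi(2*z0 -/+ z_{(1+level)/2}).
    Resamples on which the statistic is undefined (raises or returns non-
    finite) are redrawn.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("bootstrap requires at least 3 values")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = float(statistic(x))

    def evaluate(idx: np.ndarray) -> np.ndarray:
        samples = x[idx]
        try:
            out = np.asarray(statistic(samples, axis=1), dtype=float)
        except TypeError:
            out = np.array([statistic(row) for row in samples], dtype=float)
        return out

    stats = evaluate(rng.integers(0, n, size=(B, n)))
    n_redrawn = 0
    for _ in range(100):  # redraw invalid resamples, bounded
        bad = ~np.isfinite(stats)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        stats[bad] = evaluate(rng.integers(0, n, size=(int(bad.sum()), n)))
    if n_redrawn:
        logger.info("bootstrap: redrew %d invalid resamples", n_redrawn)
    if not np.isfinite(stats).all():
        raise ValueError("statistic undefined on too many bootstrap resamples")

    prop = (np.sum(stats < theta) + 0.5 * np.sum(stats == theta)) / B
    prop = min(max(prop, 0.5 / B), 1 - 0.5 / B)
    z0 = ndtri(prop)
    z = ndtri(0.5 + level / 2.0)
    p_lo = ndtr(2 * z0 - z)
    p_hi = ndtr(2 * z0 + z)
    lo, hi = np.quantile(stats, [p_lo, p_hi])
    return float(lo), float(hi)


@dataclass(frozen=True)
class NoiseDecomposition:
    """Dual-reporter noise decomposition (Elowitz-style).

    ``eta_ext2`` keeps its sign when the sampling estimate is negative; in
    that case ``eta_ext`` is reported as 0 and ``ext_negative`` is set.  The
    identity eta_tot^2 = eta_int^2 + eta_ext^2 holds exactly on the signed
    squared values.
    """

    eta_int: float
    eta_ext: float
    eta_tot: float
    eta_int2: float
    eta_ext2: float
    eta_tot2: float
    n_cells: int
    ext_negative: bool = False


def elowitz_decompose(c1, c2, mean_normalize: bool = True) -> NoiseDecomposition:
    """Intrinsic/extrinsic noise levels from two reporter channels.

    eta_int^2 = <(c1-c2)^2> / (2 <c1><c2>);
    eta_ext^2 = (<c1 c2> - <c1><c2>) / (<c1><c2>);
    eta_tot^2 = their sum.
    ``mean_normalize`` divides each channel by its mean first, which makes the
    decomposition meaningful for pseudo two-colour channels with unequal
    gains (e.g. nucleus vs cytoplasm of one reporter).
    """
    x = np.asarray(c1, dtype=float)
    y = np.asarray(c2, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("channels must have equal length >= 3")
    mx, my = x.mean(), y.mean()
    if mx <= 0 or my <= 0:
        raise ValueError("channel means must be strictly positive")
    if mean_normalize:
        x, y = x / mx, y / my
        mx = my = 1.0
    denom = mx * my
    eta_int2 = float(np.mean((x - y) ** 2) / (2 * denom))
    eta_ext2 = float((np.mean(x * y) - denom) / denom)
    eta_tot2 = eta_int2 + eta_ext2
    ext_negative = eta_ext2 < 0
    return NoiseDecomposition(
        eta_int=math.sqrt(max(eta_int2, 0.0)),
        eta_ext=0.0 if ext_negative else math.sqrt(eta_ext2),
        eta_tot=math.sqrt(max(eta_tot2, 0.0)),
        eta_int2=eta_int2,
        eta_ext2=eta_ext2,
        eta_tot2=eta_tot2,
        n_cells=int(x.size),
        ext_negative=ext_negative,
    )


@dataclass(frozen=True)
class CorrelationTest:
    r: float
    t: float
    df: int
    p: float


def t_from_r(r: float, df: int) -> float:
    """t statistic for a Pearson coefficient: t = r * sqrt(df / (1 - r^2))."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return r * math.sqrt(df / (1.0 - r * r))


def pearson_test(x, y) -> CorrelationTest:
    """Pearson correlation with a two-sided t-test on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0 or sy == 0:
        raise ValueError("constant input has no defined correlation")
    r = float(dx @ dy) / (sx * sy)
    r = max(min(r, 1.0), -1.0)
    df = x.size - 2
    if abs(r) == 1.0:
        t_stat, p = math.copysign(math.inf, r), 0.0
    else:
        t_stat = t_from_r(r, df)
        p = float(2 * t_dist.sf(abs(t_stat), df))
    return CorrelationTest(r=r, t=t_stat, df=df, p=p)


def nc_ratio(nuclear_mean: float, cytoplasm_median: float) -> float:
    """Nuclear-to-cytoplasm signal ratio (mean nuclear / median cytoplasmic)."""
    if cytoplasm_median <= 0:
        raise ValueError("cytoplasm_median must be strictly positive")
    return nuclear_mean / cytoplasm_median
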