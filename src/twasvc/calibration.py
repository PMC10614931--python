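"""Calibration diagnostics: Z-score variance, uniformity tests, QQ data.

The headline diagnostic is the sample variance of Z-scores over many null
associations, computed about 0 (i.e. the average Z^2, the quantity whose
linear growth in N*h2 defines the inflation slope).  A calibrated test keeps
it inside the sampling interval of a mean of chi-square(1) variables and its
p-values uniform on (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


def z_sample_variance(z: Sequence[float], center: bool = False) -> float:
    """Mean of Z^2 (variance about 0); ``center=True`` subtracts the mean."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 Z-scores")
    if center:
        z = z - z.mean()
    return float(np.mean(z ** 2))


def null_variance_interval(n: int, level: float = 0.95,
                           method: str = "normal") -> Tuple[float, float]:
    """Central interval of the mean of n i.i.d. chi-square(1) variables.

    ``method='normal'`` uses mean 1, sd sqrt(2/n); ``method='exact'`` uses the
    chi-square(n)/n quantiles.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    if method == "normal":
        half = stats.norm.ppf(1.0 - tail) * np.sqrt(2.0 / n)
        return (1.0 - half, 1.0 + half)
    if method == "exact":
        return (float(stats.chi2.ppf(tail, n) / n),
                float(stats.chi2.ppf(1.0 - tail, n) / n))
    raise ValueError("method must be 'normal' or 'exact'")


def uniformity_test(p: Sequence[float]) -> Tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against Uniform(0, 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def qq_points(p: Sequence[float], n_points: int = 1000) -> List[Tuple[float, float]]:
    """(expected, observed) -log10 p-value quantile pairs for a QQ plot.

    Observed order statistics are matched to uniform expected quantiles
    i/(n+1) and thinned to at most ``n_points`` pairs, sorted by expected
    quantile.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    n = p.size
    order = np.sort(p)
    expected = np.arange(1, n + 1) / (n + 1.0)
    exp_l = -np.log10(expected)
    obs_l = -np.log10(np.maximum(order, np.finfo(float).tiny))
    if n_points < n:
        keep = np.unique(np.linspace(0, n - 1, n_points).round().astype(int))
    else:
        keep = np.arange(n)
    pairs = list(zip(exp_l[keep], obs_l[keep]))
    pairs.sort(key=lambda t: t[0])
    return pairs


def qq_band(n: int, n_points: int = 1000,
            level: float = 0.95) -> List[Tuple[float, float, float]]:
    """Pointwise beta-distribution confidence band for a uniform QQ plot.

    Returns (expected, lower, upper) on the -log10 scale: the i-th order
    statistic of n uniforms is Beta(i, n - i + 1).
    """
    ranks = np.arange(1, n + 1)
    if n_points < n:
        ranks = np.unique(np.linspace(1, n, n_points).round().astype(int))
    tail = (1.0 - level) / 2.0
    expected = -np.log10(ranks / (n + 1.0))
    lo = -np.log10(stats.beta.ppf(1.0 - tail, ranks, n - ranks + 1))
    hi = -np.log10(stats.beta.ppf(tail, ranks, n - ranks + 1))
    out = list(zip(expected, lo, hi))
    out.sort(key=lambda t: t[0])
    return out


@dataclass
class CalibrationReport:
    """Summary of how calibrated a set of null associations is."""

    n_tests: int
    z_sample_variance: float
    z_var_null_interval: Tuple[float, float]
    ks_stat: float
    ks_p: float
    qq_points: List[Tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "n_tests": self.n_tests,
            "z_sample_variance": self.z_sample_variance,
            "z_var_null_interval": list(self.z_var_null_interval),
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
        }


def make_report(z: Sequence[float], p: Optional[Sequence[float]] = None,
                level: float = 0.95, n_qq_points: int = 1000) -> CalibrationReport:
    """Build a CalibrationReport from Z-scores (p-values derived if absent)."""
    z = np.asarray(z, dtype=float)
    if p is None:
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.maximum(p, np.finfo(float).tiny)
    ks_stat, ks_p = uniformity_test(p)
    return CalibrationReport(
        n_tests=int(z.shape[0]),
        z_sample_variance=z_sample_variance(z),
        z_var_null_interval=null_variance_interval(z.shape[0], level=level),
        ks_stat=ks_stat,
        ks_p=ks_p,
        qq_points=qq_points(p, n_points=n_qq_points),
    )
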