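"""Convergence-validity checks for a completed chain.

A chain is considered converged when (i) the lag-1 autocorrelation of every
monitored stored series is below 0.1, (ii) the series show no trend (a
Geweke-style first-10%-vs-last-50% z-statistic as a reproducible stand-in
for visual trace inspection), and (iii) the posterior densities look
roughly normal (moment-based skewness/kurtosis screens).  The overall pass
flag depends on the autocorrelation rule and the trend check; normality is
reported but informational.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def lag1_autocorrelation(series, warn: bool = True) -> float:
    """Sample autocorrelation at lag 1 (mean-centered, biased-normalized).

    A constant series has undefined autocorrelation; by convention it is
    reported as 0 with a warning.
    """
    x = np.asarray(series, float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        if warn:
            warnings.warn("constant series: lag-1 autocorrelation set to 0")
        return 0.0
    return float(xc[:-1] @ xc[1:]) / denom


def _spectral_var(x: np.ndarray) -> float:
    """Spectral density of the series at frequency zero (Bartlett window)."""
    n = x.size
    xc = x - x.mean()
    g0 = float(xc @ xc) / n
    if g0 == 0.0:
        return 0.0
    L = max(int(np.sqrt(n)), 1)
    s = g0
    for k in range(1, L + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gk
    return max(s, 0.0)


def trend_check(series, z_threshold: float = 2.0) -> tuple[float, bool]:
    """Geweke comparison of the first 10% vs the last 50% of the chain.

    Returns ``(z, flagged)``; |z| at or above the threshold flags a trend.
    Segment means are scaled by spectral-density standard errors so the
    statistic is robust to within-chain autocorrelation.
    """
    x = np.asarray(series, float)
    if x.size < 50:
        raise ValueError("need at least 50 stored samples")
    a = x[: max(int(0.1 * x.size), 10)]
    b = x[int(0.5 * x.size):]
    va = _spectral_var(a) / a.size
    vb = _spectral_var(b) / b.size
    denom = np.sqrt(va + vb)
    z = 0.0 if denom == 0.0 else float((a.mean() - b.mean()) / denom)
    return z, abs(z) >= z_threshold


def normality_check(series, skew_threshold: float = 1.0,
                    kurt_threshold: float = 2.0) -> tuple[float, float, bool]:
    """Moment screen: flag |skewness| > 1 or |excess kurtosis| >= 2.

    The kurtosis bound is inclusive so the extreme platykurtic case (a
    symmetric two-point mass, excess kurtosis exactly -2) is flagged.
    """
    x = np.asarray(series, float)
    if x.size < 100:
        raise ValueError("need at least 100 stored samples")
    if np.std(x) == 0.0:
        return 0.0, -3.0, True       # point mass: maximally non-normal
    sk = float(stats.skew(x))
    ku = float(stats.kurtosis(x))    # excess kurtosis
    return sk, ku, (abs(sk) > skew_threshold) or (abs(ku) >= kurt_threshold)


@dataclass
class ConvergenceReport:
    """Per-parameter diagnostics plus the overall pass flag.

    ``passed`` is true iff every monitored lag-1 autocorrelation is below
    the threshold (default 0.1) and no trend is flagged.
    """

    autocorr: dict = field(default_factory=dict)
    trend_z: dict = field(default_factory=dict)
    trend_flag: dict = field(default_factory=dict)
    skewness: dict = field(default_factory=dict)
    kurtosis: dict = field(default_factory=dict)
    normality_flag: dict = field(default_factory=dict)
    autocorr_threshold: float = 0.1
    passed: bool = False

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)

    @classmethod
    def from_series(cls, series: dict, autocorr_threshold: float = 0.1) -> "ConvergenceReport":
        rep = cls(autocorr_threshold=autocorr_threshold)
        for name, x in series.items():
            x = np.asarray(x, float)
            rep.autocorr[name] = lag1_autocorrelation(x, warn=False)
            z, tf = trend_check(x)
            rep.trend_z[name] = z
            rep.trend_flag[name] = bool(tf)
            if x.size >= 100:
                sk, ku, nf = normality_check(x)
                rep.skewness[name] = sk
                rep.kurtosis[name] = ku
                rep.normality_flag[name] = bool(nf)
        # signed comparison: negative lag-1 autocorrelation means faster
        # than independent mixing and is not a convergence failure
        rep.passed = all(v < autocorr_threshold for v in rep.autocorr.values()) \
            and not any(rep.trend_flag.values())
        return rep


def convergence_report(chain, autocorr_threshold: float = 0.1) -> ConvergenceReport:
    """Diagnose a fitted chain, monitoring variance components and fixed
    effects (the parameters whose traces gate downstream summaries)."""
    series = {**chain.variance_series(), **chain.fixed_series()}
    return ConvergenceReport.from_series(series, autocorr_threshold)
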