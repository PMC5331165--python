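"""Test-retest repeatability statistics.

The headline summary is the repeatability coefficient: the half-width of
the 95% limits of agreement between paired test-retest measurements.

* parametric:     RPC    = 1.96 * SD(differences)
* nonparametric:  RPC_np = 1.45 * IQR(differences)

For normally distributed differences the two coincide: the standard-normal
IQR is 2 * Phi^{-1}(0.75) = 1.349, and 1.96 / 1.349 = 1.45 (2 d.p.).  The
nonparametric form is robust to the flow-difference outliers typical of
patient data.  Systematic test-retest bias is removed by forcing the
per-condition median difference to zero before computing coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "rpc_multiplier_np",
    "rpc_multiplier",
    "rpc",
    "rpc_np",
    "median_center",
    "relative_differences",
    "bland_altman",
    "BlandAltman",
    "spearman_rho",
    "wilcoxon_p",
    "levene_p",
    "rpp_adjust",
    "REST_RPP_POPULATION",
    "STRESS_RPP_POPULATION",
]

#: Population-average rate-pressure products (bpm x mmHg) for workload
#: normalization of MBF.
REST_RPP_POPULATION = 8240.0
STRESS_RPP_POPULATION = 10638.0


def rpc_multiplier() -> float:
    """97.5% standard-normal quantile — the parametric limits-of-agreement factor."""
    return float(stats.norm.ppf(0.975))


def rpc_multiplier_np() -> float:
    """IQR-to-95%-limits factor: 1.96 / (standard-normal IQR), ~= 1.45."""
    iqr_normal = float(stats.norm.ppf(0.75) - stats.norm.ppf(0.25))
    return rpc_multiplier() / iqr_normal


def rpc(d) -> float:
    """Parametric repeatability coefficient, 1.96 x sample SD (ddof=1)."""
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("RPC needs at least 2 differences")
    return 1.96 * float(np.std(d, ddof=1))


def rpc_np(d) -> float:
    """Nonparametric repeatability coefficient, 1.45 x IQR.

    Quartiles by linear interpolation of order statistics (numpy's default
    'linear' / Hyndman-Fan type 7 rule).
    """
    d = np.asarray(d, dtype=float)
    if d.size < 4:
        raise ValueError("RPC_np needs at least 4 differences")
    q1, q3 = np.quantile(d, [0.25, 0.75])
    return 1.45 * float(q3 - q1)


def median_center(d, condition) -> np.ndarray:
    """Subtract the per-condition median difference (bias removal).

    The median of each condition's centered differences is exactly zero, and
    the operation is idempotent.
    """
    d = np.asarray(d, dtype=float)
    condition = np.asarray(condition)
    if condition.shape != d.shape:
        raise ValueError("condition labels must cover every difference")
    out = d.copy()
    for c in np.unique(condition):
        m = condition == c
        out[m] -= np.median(d[m])
    return out


def relative_differences(test, retest):
    """Percent differences relative to the pair means.

    Returns ``(percent, kept)``: rows with nonpositive pair means are
    excluded (flagged False in ``kept``) since a percent-of-mean is
    meaningless there.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    means = 0.5 * (test + retest)
    kept = means > 0
    pct = 100.0 * (retest[kept] - test[kept]) / means[kept]
    return pct, kept


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    lower: float
    upper: float
    lower_np: float
    upper_np: float
    pair_means: np.ndarray
    differences: np.ndarray


def bland_altman(test, retest, relative: bool = False) -> BlandAltman:
    """Bland-Altman agreement analysis of paired measurements.

    Parametric limits are mean +/- 1.96 SD; nonparametric limits are
    median +/- RPC_np / 2, mirroring 95% limits while using the robust
    coefficient.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.size < 4 or test.shape != retest.shape:
        raise ValueError("Bland-Altman needs >= 4 pairs")
    means = 0.5 * (test + retest)
    if relative:
        d, kept = relative_differences(test, retest)
        means = means[kept]
    else:
        d = retest - test
    md = float(np.mean(d))
    half = 1.96 * float(np.std(d, ddof=1))
    med = float(np.median(d))
    half_np = rpc_np(d) / 2.0
    return BlandAltman(md, md - half, md + half, med - half_np, med + half_np, means, d)


def spearman_rho(test, retest) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.size < 3:
        raise ValueError("Spearman correlation needs >= 3 pairs")
    if np.ptp(test) == 0 or np.ptp(retest) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(test, retest).statistic
    return float(rho)


def wilcoxon_p(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact null distribution for <= 25 nonzero differences, normal
    approximation with continuity correction above.  A single effective
    pair is degenerate and returns p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero; Wilcoxon test is degenerate")
    if nz.size == 1:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def levene_p(x, y) -> float:
    """Brown-Forsythe (median-centered Levene) p-value for equal spread."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or y.size < 4:
        raise ValueError("Levene test needs >= 4 values per group")
    if np.ptp(np.abs(x - np.median(x))) == 0 and np.ptp(np.abs(y - np.median(y))) == 0:
        if np.array_equal(np.sort(x), np.sort(y)) or (np.ptp(x) == 0 and np.ptp(y) == 0):
            return 1.0
        raise ValueError("both groups have zero spread; Levene test is degenerate")
    res = stats.levene(x, y, center="median")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def rpp_adjust(mbf, rpp_study: float, rpp_population: float):
    """Normalize MBF to the population-average rate-pressure product."""
    if rpp_study <= 0:
        raise ValueError("study RPP must be positive")
    return np.asarray(mbf, dtype=float) * (rpp_population / rpp_study) if np.ndim(mbf) else mbf * rpp_population / rpp_study
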