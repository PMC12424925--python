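"""Linear age trends on per-bin metric series, variance decomposition, and attribution.

Any per-age-bin metric series (h2, R2_obs, logHR, ...) with standard errors is
fitted with a weighted linear model value ~ N(a * age + b, se^2) and the flat
model a = 0; a likelihood-ratio test against chi-square(1) flags non-constant
series.  Slope uncertainty comes from Monte-Carlo resampling of each bin value
from N(point, se^2) — valid because age bins are disjoint samples.  The module
also decomposes per-bin phenotypic variance into genetic and environmental
parts, computes the proportion tau of observed PRS-accuracy decline explained
by a model's predicted decline, and the combined exposure-accumulation +
liability-threshold expected change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedEstimateError
from .series import MetricSeries

__all__ = [
    "TrendEstimate",
    "VarianceDecomposition",
    "fit_metric_trend",
    "relative_10yr_change",
    "variance_decomposition",
    "tau_explained",
    "combined_expected_change",
    "slope_difference_test",
]


@dataclass
class TrendEstimate:
    slope: float  # a, per year
    intercept: float  # b
    lrt_stat: float
    lrt_p: float
    slope_se: float
    mc_slopes: np.ndarray = field(repr=False, default=None)
    rel_change_10yr: float = np.nan
    rel_change_se: float = np.nan


@dataclass
class VarianceDecomposition:
    var_g: np.ndarray  # per bin, h2 * var(P)
    var_e: np.ndarray  # per bin, (1 - h2) * var(P)
    trend_g: TrendEstimate
    trend_e: TrendEstimate
    delta_var_g_10yr: float
    delta_var_g_se: float
    delta_var_e_10yr: float
    delta_var_e_se: float


def _wls_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    xb = (w * x).sum() / w.sum()
    yb = (w * y).sum() / w.sum()
    sxx = (w * (x - xb) ** 2).sum()
    a = (w * (x - xb) * (y - yb)).sum() / sxx
    return a, yb - a * xb


def fit_metric_trend(
    series: MetricSeries, n_mc: int = 1000, seed: int | np.random.Generator = 0
) -> TrendEstimate:
    """Weighted ML linear trend with LRT against a constant model.

    With known per-bin noise se_k, the ML fit of value ~ N(a*age + b, se^2) is
    weighted least squares with weights 1/se^2; the LRT statistic is the drop
    in weighted residual sum of squares, referred to chi-square(1).  The slope
    s.e. is the s.d. of slopes refitted on Monte-Carlo draws of each bin value
    from a Gaussian centred at the point estimate with s.d. equal to its s.e.
    """
    if len(series) < 3:
        raise ParameterError("need >= 3 bins for a trend fit")
    x = series.median_ages
    y = series.values
    se = series.ses
    if len(np.unique(x)) != len(x):
        raise ParameterError("median ages must be distinct")
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ParameterError("all bin standard errors must be positive and finite")
    w = 1.0 / se**2
    a, b = _wls_fit(x, y, w)
    chi2_h1 = (w * (y - (a * x + b)) ** 2).sum()
    b0 = (w * y).sum() / w.sum()
    chi2_h0 = (w * (y - b0) ** 2).sum()
    lrt = chi2_h0 - chi2_h1
    p = float(stats.chi2.sf(lrt, df=1))

    # closed-form WLS slope is linear in y: slope = c @ y
    xb = (w * x).sum() / w.sum()
    c = w * (x - xb) / (w * (x - xb) ** 2).sum()
    rng = np.random.default_rng(seed)
    draws = rng.normal(y, se, size=(n_mc, len(y)))
    mc_slopes = draws @ c
    return TrendEstimate(
        slope=float(a),
        intercept=float(b),
        lrt_stat=float(lrt),
        lrt_p=p,
        slope_se=float(mc_slopes.std(ddof=1)),
        mc_slopes=mc_slopes,
    )


def relative_10yr_change(
    trend: TrendEstimate, population_estimate: float
) -> tuple[float, float]:
    """Signed 10-year change relative to the whole-population estimate.

    10 * slope / population_estimate; the s.e. is propagated through the
    Monte-Carlo slope draws.  Returns (value, se) and stores them on the trend.
    """
    if population_estimate == 0:
        raise UndefinedEstimateError("population estimate is zero")
    value = 10.0 * trend.slope / population_estimate
    if trend.mc_slopes is not None:
        se = float((10.0 * trend.mc_slopes / population_estimate).std(ddof=1))
    else:
        se = 10.0 * trend.slope_se / abs(population_estimate)
    trend.rel_change_10yr = float(value)
    trend.rel_change_se = se
    return float(value), se


def variance_decomposition(
    h2_series: MetricSeries,
    phen_var_series: MetricSeries,
    n_mc: int = 1000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Split per-bin phenotypic variance into genetic and environmental parts.

    var(G)_k = h2_k * var(P)_k and var(E)_k = (1 - h2_k) * var(P)_k, with
    standard errors by independent error propagation; each derived series is
    then trend-fitted to give the 10-year changes whose contrast separates
    exposure accumulation (var(E) grows, var(G) flat) from proportional
    amplification (both scale together).
    """
    if len(h2_series) != len(phen_var_series):
        raise ParameterError("mismatched bins between h2 and phenotypic variance")
    if not np.allclose(h2_series.median_ages, phen_var_series.median_ages, atol=1.0):
        raise ParameterError("h2 and variance series use different age coordinates")
    h2, se_h = h2_series.values, h2_series.ses
    vp, se_v = phen_var_series.values, phen_var_series.ses
    var_g = h2 * vp
    var_e = (1.0 - h2) * vp
    se_g = np.sqrt(vp**2 * se_h**2 + h2**2 * se_v**2)
    se_e = np.sqrt(vp**2 * se_h**2 + (1.0 - h2) ** 2 * se_v**2)
    g_series = MetricSeries("var_g", var_g, se_g, h2_series.median_ages, h2_series.ns)
    e_series = MetricSeries("var_e", var_e, se_e, h2_series.median_ages, h2_series.ns)
    tg = fit_metric_trend(g_series, n_mc=n_mc, seed=seed)
    te = fit_metric_trend(e_series, n_mc=n_mc, seed=seed + 1)
    return VarianceDecomposition(
        var_g=var_g,
        var_e=var_e,
        trend_g=tg,
        trend_e=te,
        delta_var_g_10yr=10.0 * tg.slope,
        delta_var_g_se=10.0 * tg.slope_se,
        delta_var_e_10yr=10.0 * te.slope,
        delta_var_e_se=10.0 * te.slope_se,
    )


def tau_explained(delta_qrs: np.ndarray, delta_prs: np.ndarray) -> float:
    """Proportion of observed PRS-accuracy decline explained by a model.

    tau = sum_d max(dQRS_d, dPRS_d) / sum_d dPRS_d over diseases, with changes
    expressed as signed relative 10-year changes (negative = decline).  The
    elementwise max clamps any disease whose predicted decline exceeds the
    observed one, so tau <= 1 when all observed changes are declines.
    """
    dq = np.asarray(delta_qrs, dtype=float)
    dp = np.asarray(delta_prs, dtype=float)
    if dq.shape != dp.shape:
        raise ParameterError("delta lists must have equal length")
    denom = dp.sum()
    if denom == 0:
        raise UndefinedEstimateError("total PRS change is zero; tau undefined")
    return float(np.maximum(dq, dp).sum() / denom)


def combined_expected_change(
    delta_qrs: float,
    delta_h2: float,
    se_qrs: float = 0.0,
    se_h2: float = 0.0,
    n_mc: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Expected 10-year decline under the combined EA + liability-threshold model.

    1 - (1 + dR2_QRS)(1 + dh2): the QRS change carries the threshold-model
    factors, the liability-h2 change carries exposure accumulation, and under
    the EA model PRS accuracy is proportional to liability h2, so the factors
    multiply.  Positive output = decline.  The s.e. treats the two inputs as
    independent Monte-Carlo draws.
    """
    value = 1.0 - (1.0 + delta_qrs) * (1.0 + delta_h2)
    rng = np.random.default_rng(seed)
    dq = rng.normal(delta_qrs, se_qrs, n_mc) if se_qrs > 0 else np.full(n_mc, delta_qrs)
    dh = rng.normal(delta_h2, se_h2, n_mc) if se_h2 > 0 else np.full(n_mc, delta_h2)
    draws = 1.0 - (1.0 + dq) * (1.0 + dh)
    return float(value), float(draws.std(ddof=1))


def slope_difference_test(
    x: float, y: float, se_x: float, se_y: float
) -> tuple[float, float]:
    """z-test for a difference between two independent estimates."""
    se = np.sqrt(se_x**2 + se_y**2)
    if se == 0:
        return (0.0, 1.0) if x == y else (np.inf, 0.0)
    z = (x - y) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
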