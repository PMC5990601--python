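"""Linear recovery trends, trend classification, and convergence points.

Each movement parameter's daily values are modeled per body side as
y = alpha + beta * t with t in days since study begin (day 1 = first
recording).  The convergence point (CP) is the day at which the affected
and non-affected trend lines intersect,

    CP = (alpha_Aff - alpha_NonAff) / (beta_NonAff - beta_Aff),

evaluated over t = 1..t_max with t_max = 3650 days (10 years); a CP
outside that span, or parallel trends, are reported as capped/parallel.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import ConvergencePoint, TrendModel

T_MAX_DAYS = 3650.0


def fit_linear_trend(t: np.ndarray, y: np.ndarray, parameter: str = "",
                     role: str = "Aff") -> TrendModel:
    """Ordinary least-squares trend over recording days.

    Days without walking data (NaN values) are omitted, not zero-filled.
    A zero-variance response gets beta = 0 and R^2 defined as 0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(t)
    t, y = t[ok], y[ok]
    if t.size < 2:
        raise ValueError("need at least two days with defined values")
    if np.all(t == t[0]):
        raise ValueError("all day indices identical")
    if np.var(y) == 0.0:
        return TrendModel(parameter=parameter, role=role, alpha=float(y[0]),
                          beta=0.0, r_squared=0.0, n_days=t.size)
    res = stats.linregress(t, y)
    return TrendModel(parameter=parameter, role=role,
                      alpha=float(res.intercept), beta=float(res.slope),
                      r_squared=float(res.rvalue ** 2), n_days=t.size)


def convergence_point(model_aff: TrendModel, model_nonaff: TrendModel,
                      t_max: float = T_MAX_DAYS) -> ConvergencePoint:
    """Intersection day of the two side trends, with the 10-year cut-off."""
    if model_aff.parameter != model_nonaff.parameter:
        raise ValueError("models fitted on different parameters")
    name = model_aff.parameter
    if model_aff.beta == model_nonaff.beta:
        return ConvergencePoint(parameter=name, t_cp=float("nan"),
                                classification="parallel", t_max=t_max)
    t_cp = (model_aff.alpha - model_nonaff.alpha) / (
        model_nonaff.beta - model_aff.beta)
    if not (1.0 <= t_cp <= t_max):
        return ConvergencePoint(parameter=name, t_cp=float("nan"),
                                classification="capped", t_max=t_max)
    return ConvergencePoint(parameter=name, t_cp=float(t_cp),
                            classification="converging", t_max=t_max)


def classify_trend(t: np.ndarray, y_aff: np.ndarray, y_nonaff: np.ndarray,
                   model_aff: TrendModel | None = None,
                   model_nonaff: TrendModel | None = None,
                   alpha: float = 0.05,
                   t_max: float = T_MAX_DAYS) -> str | None:
    """Classify the recovery trend as parallel, converging or diverging.

    Parallel iff the Pearson correlation between the sides' daily values is
    positive with p < 0.05 (or the fitted slopes are exactly equal);
    otherwise converging iff the trend lines intersect within the 10-year
    horizon [1, t_max] — a crossing before the last observed day means
    convergence was already achieved — else diverging.  Returns None for
    fewer than three common days.
    """
    t = np.asarray(t, dtype=float)
    y_aff = np.asarray(y_aff, dtype=float)
    y_nonaff = np.asarray(y_nonaff, dtype=float)
    ok = ~np.isnan(y_aff) & ~np.isnan(y_nonaff)
    t, y_aff, y_nonaff = t[ok], y_aff[ok], y_nonaff[ok]
    if t.size < 3:
        return None
    if np.std(y_aff) > 0 and np.std(y_nonaff) > 0:
        r, p = stats.pearsonr(y_aff, y_nonaff)
        if r > 0 and p < alpha:
            return "parallel"
    if model_aff is None:
        model_aff = fit_linear_trend(t, y_aff, role="Aff")
    if model_nonaff is None:
        model_nonaff = fit_linear_trend(t, y_nonaff, role="NonAff")
    if model_aff.beta == model_nonaff.beta:
        return "parallel"
    t_cp = (model_aff.alpha - model_nonaff.alpha) / (
        model_nonaff.beta - model_aff.beta)
    return "converging" if 1.0 <= t_cp <= t_max else "diverging"


def continuous_convergence(t: np.ndarray, y_aff: np.ndarray,
                           y_nonaff: np.ndarray, parameter: str = "",
                           t_max: float = T_MAX_DAYS) -> list[ConvergencePoint]:
    """Growing-window CP series: one CP per window of the first k days.

    Windows start at two days (k = 2..K); each refits both side trends on
    days 1..k and intersects them.
    """
    t = np.asarray(t, dtype=float)
    y_aff = np.asarray(y_aff, dtype=float)
    y_nonaff = np.asarray(y_nonaff, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two recording days")
    cps = []
    for k in range(2, t.size + 1):
        ma = fit_linear_trend(t[:k], y_aff[:k], parameter, "Aff")
        mn = fit_linear_trend(t[:k], y_nonaff[:k], parameter, "NonAff")
        cps.append(convergence_point(ma, mn, t_max=t_max))
    return cps


def side_difference_test(y_aff: np.ndarray, y_nonaff: np.ndarray) -> float:
    """Paired two-sided t-test p-value for the side difference.

    Identical series give p = 1 (t = 0); a zero-variance nonzero difference
    leaves p undefined (NaN).
    """
    y_aff = np.asarray(y_aff, dtype=float)
    y_nonaff = np.asarray(y_nonaff, dtype=float)
    ok = ~np.isnan(y_aff) & ~np.isnan(y_nonaff)
    d = y_aff[ok] - y_nonaff[ok]
    if d.size < 2:
        raise ValueError("need at least two paired days")
    if np.std(d, ddof=1) == 0.0:
        return 1.0 if np.all(d == 0.0) else float("nan")
    return float(stats.ttest_rel(y_aff[ok], y_nonaff[ok]).pvalue)
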