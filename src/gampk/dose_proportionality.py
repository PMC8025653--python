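"""Dose-proportionality power model and two-sample comparisons.

The power model regresses ln(AUCinf) on ln(dose),

    ln AUCinf = β0 + β1 · ln Dose,

by weighted least squares with per-observation weight 1/dose (exposure
variance grows with dose); β1 = 1 indicates perfectly dose-proportional
exposure. AUC enters on the ng·hr/ml scale. Confidence limits are at 95%.

Two-sample comparisons (sex differences; dose-normalized AUC between dose
groups) use Student's t — pooled variance by default, Welch optionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class PowerModelFit:
    """Weighted log-log regression estimates with CIs and diagnostics."""

    beta0: float
    beta1: float
    r_squared: float
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float]
    p_value_beta0: float
    p_value_beta1: float
    n: int
    residual_mean: float
    residual_normality_p: float
    weighted: bool


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant_at_95: bool


def fit_power_model(
    observations: Sequence[tuple[float, float]],
    *,
    weight_by_inverse_dose: bool = True,
) -> PowerModelFit:
    """Fit the power model to (dose mg/kg, AUCinf ng·hr/ml) pairs.

    Requires >= 3 observations spanning >= 2 distinct doses; the slope is
    unidentifiable otherwise.
    """
    obs = list(observations)
    if len(obs) < 3:
        raise ValueError("fit_power_model: need at least 3 observations")
    doses = np.array([d for d, _ in obs], dtype=float)
    aucs = np.array([a for _, a in obs], dtype=float)
    if np.any(doses <= 0) or np.any(aucs <= 0):
        raise ValueError("fit_power_model: doses and AUCs must be positive")
    if len(np.unique(doses)) < 2:
        raise ValueError("fit_power_model: single distinct dose, slope unidentifiable")

    y = np.log(aucs)
    X = sm.add_constant(np.log(doses))
    weights = 1.0 / doses if weight_by_inverse_dose else np.ones_like(doses)
    fit = sm.WLS(y, X, weights=weights).fit()

    ci = fit.conf_int(alpha=0.05)
    resid = np.asarray(fit.resid)
    # Shapiro-Wilk as the residual normality check; degenerate (all-equal)
    # residuals from an exact fit give an uninformative NaN
    if len(resid) >= 3 and np.ptp(resid) > 1e-12:
        normality_p = float(stats.shapiro(resid).pvalue)
    else:
        normality_p = float("nan")
    return PowerModelFit(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        ci_beta0=(float(ci[0][0]), float(ci[0][1])),
        ci_beta1=(float(ci[1][0]), float(ci[1][1])),
        p_value_beta0=float(fit.pvalues[0]),
        p_value_beta1=float(fit.pvalues[1]),
        n=len(obs),
        residual_mean=float(resid.mean()),
        residual_normality_p=normality_p,
        weighted=weight_by_inverse_dose,
    )


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> TTestResult:
    """Two-sided Student's t test (pooled variance unless ``welch``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two_sample_ttest: each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
    else:
        df = len(a) + len(b) - 2
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(df),
        p_value=float(res.pvalue),
        significant_at_95=bool(res.pvalue < 0.05),
    )
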