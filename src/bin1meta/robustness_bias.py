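"""Sensitivity analysis and publication-bias diagnostics.

* leave-one-out: re-run heterogeneity + random-effects pooling k times,
  each omitting one study, to show no single study drives the result;
* funnel-plot coordinates (effect vs standard error, with the pseudo-95%
  confidence triangle around the pooled effect);
* Egger's regression test: OLS of the standard normal deviate theta/se on
  precision 1/se; a non-zero intercept indicates small-study asymmetry;
* Begg-Mazumdar rank correlation: Kendall tau between standardised
  deviates from the fixed-effect mean and their variances, with the exact
  null variance k(k-1)(2k+5)/18, tie adjustment, and continuity correction.

Both bias tests report raw p-values; the package-wide significance level
for them is 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effect_models import Z95, EffectEstimate
from .errors import InsufficientStudiesError, ValidationError
from .meta_engine import HeterogeneityResult, PooledResult, cochran_q, pool_random_dl

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of a funnel-asymmetry test.

    ``statistic`` is Kendall's tau for Begg and the regression intercept for
    Egger; ``se`` is the intercept's standard error (Egger only); ``df`` is
    k-2 for Egger's t and None for Begg's normal z.
    """

    method: str  # begg | egger
    statistic: float
    t_or_z: float
    p: float
    se: float | None = None
    df: int | None = None


@dataclass(frozen=True)
class LeaveOneOutRow:
    excluded_label: str
    het: HeterogeneityResult
    pooled: PooledResult


def leave_one_out(effects: list[EffectEstimate]) -> list[LeaveOneOutRow]:
    """Random-effects re-analysis omitting each study in turn, in input order.

    tau^2 is re-estimated on every k-1 subset, so each row's I^2 and
    heterogeneity p refer to the reduced set.
    """
    if len(effects) < 3:
        raise InsufficientStudiesError(f"leave-one-out needs k >= 3, got {len(effects)}")
    rows = []
    for i, excluded in enumerate(effects):
        rest = effects[:i] + effects[i + 1:]
        pooled = pool_random_dl(rest)
        rows.append(LeaveOneOutRow(excluded_label=excluded.label, het=pooled.het, pooled=pooled))
    return rows


def leave_one_out_table(rows: list[LeaveOneOutRow]) -> pd.DataFrame:
    """Tidy frame mirroring a sensitivity table: excluded study, I^2, het-p, OR, CI, meta-p."""
    return pd.DataFrame(
        {
            "excluded": [r.excluded_label for r in rows],
            "i_squared": [r.het.i_squared for r in rows],
            "het_p": [r.het.p for r in rows],
            "or": [r.pooled.odds_ratio for r in rows],
            "ci_low": [r.pooled.ci_low for r in rows],
            "ci_high": [r.pooled.ci_high for r in rows],
            "meta_p": [r.pooled.p for r in rows],
        }
    )


def egger_test(effects: list[EffectEstimate], weighted: bool = False) -> BiasTestResult:
    """Egger's regression asymmetry test.

    Classic (unweighted) form: regress z_i = theta_i/se_i on precision
    1/se_i by OLS; the intercept estimates asymmetry and is tested against
    a Student t with k-2 df.  ``weighted=True`` fits the equivalent
    weighted regression of theta_i on se_i with weights 1/se_i^2.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3, got {k}")
    theta = np.array([e.ln_or for e in effects])
    se = np.array([e.se for e in effects])
    if weighted:
        X = sm.add_constant(se)
        fit = sm.WLS(theta, X, weights=1.0 / se**2).fit()
    else:
        X = sm.add_constant(1.0 / se)
        fit = sm.OLS(theta / se, X).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.sum((theta / se) ** 2))):
        # perfect fit: no residual scale to test against
        if abs(float(fit.params[0])) < 1e-10:
            return BiasTestResult(method="egger", statistic=0.0, se=0.0, t_or_z=0.0, p=1.0, df=k - 2)
        raise ValidationError("degenerate Egger regression: perfect fit with non-zero intercept")
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    t = float(fit.tvalues[0])
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return BiasTestResult(method="egger", statistic=intercept, se=se_int, t_or_z=t, p=p, df=k - 2)


def begg_test(effects: list[EffectEstimate]) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation asymmetry test.

    Standardises each effect against the fixed-effect mean using
    v_i = se_i^2 - 1/sum(w) (the variance of theta_i - theta_hat), then
    computes Kendall's tau between the standardised deviates and v_i.  The
    z statistic uses the exact variance of Kendall's S under the null,
    k(k-1)(2k+5)/18, reduced by the standard tie terms when ties occur,
    with a continuity correction of 1.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test needs k >= 3, got {k}")
    theta = np.array([e.ln_or for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / se**2
    mu = float(np.sum(w * theta) / np.sum(w))
    v = se**2 - 1.0 / np.sum(w)
    if np.any(v <= 0):
        log.warning("Begg's test: %d non-positive deviate variances; falling back to se^2", int(np.sum(v <= 0)))
        v = se**2
    t_std = (theta - mu) / np.sqrt(v)

    tau = float(stats.kendalltau(t_std, v).statistic)
    # Kendall's S (concordant minus discordant pairs)
    s = 0
    for i in range(k):
        s += int(np.sum(np.sign((t_std[i] - t_std[i + 1:]) * (v[i] - v[i + 1:]))))
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    for ranks in (t_std, v):
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
        if tie_term:
            log.info("Begg's test: tie adjustment applied")
            var_s -= tie_term
    z = 0.0 if s == 0 else (abs(s) - 1.0) / np.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BiasTestResult(method="begg", statistic=tau, t_or_z=float(z), p=p)


def funnel_data(effects: list[EffectEstimate], pooled: PooledResult, n_bound_points: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Funnel-plot coordinates and the pseudo-95% confidence triangle.

    Returns (points, bounds): per-study (label, ln_or, se, odds_ratio) and,
    over the se range [0, max(se)], the bounds pooled.ln_or -/+ 1.959964*se.
    The se axis is conventionally drawn inverted (largest se at the bottom).
    """
    points = pd.DataFrame(
        {
            "label": [e.label for e in effects],
            "group": [e.group for e in effects],
            "ln_or": [e.ln_or for e in effects],
            "se": [e.se for e in effects],
            "odds_ratio": [e.odds_ratio for e in effects],
        }
    )
    se_grid = np.linspace(0.0, float(points["se"].max()), n_bound_points)
    bounds = pd.DataFrame(
        {
            "se": se_grid,
            "center": pooled.ln_or,
            "lower": pooled.ln_or - Z95 * se_grid,
            "upper": pooled.ln_or + Z95 * se_grid,
        }
    )
    return points, bounds
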