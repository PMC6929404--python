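"""Heterogeneity testing and fixed/random-effects pooling.

Implements the classical toolkit for pooling per-study log odds ratios:

* Cochran's Q with inverse-variance weights, chi-square on k-1 df;
* I^2 = (Q - (k-1)) / Q * 100, clamped to [0, 100];
* inverse-variance fixed-effect pooling;
* Mantel-Haenszel fixed-effect pooling of 2x2 tables with the
  Robins-Breslow-Greenland variance for ln(OR_MH);
* DerSimonian-Laird random effects with the method-of-moments tau^2;
* the Z test for the pooled effect;
* the model-selection rule: random effects when the heterogeneity test has
  p < 0.05 AND I^2 > 50%, fixed effect otherwise (the looser "p < 0.05 or
  I^2 > 50%" flag used to *declare* heterogeneity is carried alongside).

All confidence intervals are 95%, using the normal quantile 1.959964 on the
log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effect_models import Z95, EffectEstimate, TwoByTwoTable, build_effects
from .errors import DegenerateTableError, InsufficientStudiesError
from .study_io import StudyTable


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q, its df and p-value, and the derived I^2 (percent)."""

    q: float
    df: int
    p: float
    i_squared: float

    @property
    def significant_and(self) -> bool:
        """Heterogeneity by the pooling rule: p < 0.05 AND I^2 > 50%."""
        return self.p < 0.05 and self.i_squared > 50.0

    @property
    def significant_or(self) -> bool:
        """Heterogeneity by the declaration rule: p < 0.05 OR I^2 > 50%."""
        return self.p < 0.05 or self.i_squared > 50.0


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its uncertainty and provenance.

    ``weights`` are the per-study pooling weights normalised to sum to 1,
    in input order.  ``tau2`` is the between-study variance on the
    log-odds^2 scale (0 for fixed-effect models).
    """

    model: str  # fixed_iv | fixed_mh | random_dl
    ln_or: float
    se: float
    z: float
    p: float
    tau2: float
    weights: tuple[float, ...]
    het: HeterogeneityResult | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.ln_or))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.ln_or - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.ln_or + Z95 * self.se))

    @property
    def k(self) -> int:
        return len(self.weights)


def _unpack(effects: list[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([e.ln_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    return theta, se


def z_test(ln_or: float, se: float) -> tuple[float, float]:
    """Z statistic and two-sided normal p for a pooled log odds ratio."""
    if not se > 0:
        raise ValueError("se must be positive")
    z = ln_or / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def i_squared(q: float, k: int) -> float:
    """I^2 = (Q - (k-1)) / Q * 100%, clamped to [0, 100]; 0 at Q = 0."""
    if k < 2:
        raise InsufficientStudiesError("I^2 needs at least 2 studies")
    if q < 0:
        raise ValueError("Q cannot be negative")
    if q == 0.0:
        return 0.0
    return float(min(100.0, max(0.0, (q - (k - 1)) / q * 100.0)))


def cochran_q(effects: list[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test with inverse-variance weights."""
    if len(effects) < 2:
        raise InsufficientStudiesError(f"Cochran's Q needs k >= 2, got {len(effects)}")
    theta, se = _unpack(effects)
    w = 1.0 / se**2
    mu = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - mu) ** 2))
    df = len(effects) - 1
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, p=p, i_squared=i_squared(q, len(effects)))


def pool_fixed_iv(effects: list[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling."""
    if not effects:
        raise InsufficientStudiesError("no effects to pool")
    theta, se = _unpack(effects)
    w = 1.0 / se**2
    ln_or = float(np.sum(w * theta) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    z, p = z_test(ln_or, se_pooled)
    het = cochran_q(effects) if len(effects) >= 2 else None
    return PooledResult(
        model="fixed_iv", ln_or=ln_or, se=se_pooled, z=z, p=p, tau2=0.0,
        weights=tuple(w / np.sum(w)), het=het,
    )


def pool_fixed_mh(tables: list[TwoByTwoTable]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR over 2x2 tables.

    OR_MH = sum(a_i d_i / T_i) / sum(b_i c_i / T_i); the variance of
    ln(OR_MH) uses the Robins-Breslow-Greenland estimator.
    """
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    a = np.array([t.a for t in tables], float)
    b = np.array([t.b for t in tables], float)
    c = np.array([t.c for t in tables], float)
    d = np.array([t.d for t in tables], float)
    n = a + b + c + d
    R = a * d / n
    S = b * c / n
    sum_r, sum_s = float(np.sum(R)), float(np.sum(S))
    if sum_r == 0.0 or sum_s == 0.0:
        raise DegenerateTableError("Mantel-Haenszel OR undefined: a*d or b*c vanish in every table")
    ln_or = float(np.log(sum_r / sum_s))
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        np.sum(P * R) / (2.0 * sum_r**2)
        + np.sum(P * S + Q * R) / (2.0 * sum_r * sum_s)
        + np.sum(Q * S) / (2.0 * sum_s**2)
    )
    se = float(np.sqrt(var))
    z, p = z_test(ln_or, se)
    # MH weights are proportional to b_i c_i / T_i on the OR scale
    w = S / sum_s if sum_s > 0 else np.full_like(S, 1.0 / len(S))
    return PooledResult(model="fixed_mh", ln_or=ln_or, se=se, z=z, p=p, tau2=0.0, weights=tuple(w), het=None)


def dl_tau_squared(effects: list[EffectEstimate]) -> tuple[float, HeterogeneityResult]:
    """DerSimonian-Laird method-of-moments tau^2 (clamped at 0) and the Q result."""
    het = cochran_q(effects)
    _, se = _unpack(effects)
    w = 1.0 / se**2
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (het.q - het.df) / denom) if denom > 0 else 0.0
    return tau2, het


def pool_random_dl(effects: list[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    Re-weights each study by 1 / (se_i^2 + tau^2); reduces exactly to
    inverse-variance fixed-effect pooling when tau^2 = 0.
    """
    if len(effects) < 2:
        raise InsufficientStudiesError(f"random-effects pooling needs k >= 2, got {len(effects)}")
    theta, se = _unpack(effects)
    tau2, het = dl_tau_squared(effects)
    w = 1.0 / (se**2 + tau2)
    ln_or = float(np.sum(w * theta) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    z, p = z_test(ln_or, se_pooled)
    return PooledResult(
        model="random_dl", ln_or=ln_or, se=se_pooled, z=z, p=p, tau2=tau2,
        weights=tuple(w / np.sum(w)), het=het,
    )


def select_model(
    het: HeterogeneityResult, p_threshold: float = 0.05, i2_threshold: float = 50.0
) -> str:
    """Pooling-model rule: random effects iff het p < 0.05 AND I^2 > 50%."""
    return "random_dl" if (het.p < p_threshold and het.i_squared > i2_threshold) else "fixed"


def pool_auto(effects: list[EffectEstimate], p_threshold: float = 0.05, i2_threshold: float = 50.0) -> PooledResult:
    """Pool with the model chosen by :func:`select_model`."""
    het = cochran_q(effects)
    if select_model(het, p_threshold, i2_threshold) == "random_dl":
        return pool_random_dl(effects)
    return pool_fixed_iv(effects)


@dataclass
class SubgroupAnalysis:
    """Per-group heterogeneity + pooling, plus the pooled-over-all result."""

    by_group: dict[str, PooledResult]
    overall: PooledResult
    skipped: dict[str, int] = field(default_factory=dict)  # group -> k, for groups with < 2 studies

    def table(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        """A tidy frame: one column per group plus 'all'; rows I^2, het-p, OR, CI, meta-p."""
        import pandas as pd

        cols = {}
        for name, res in {**self.by_group, "all": self.overall}.items():
            cols[name] = {
                "k": res.k,
                "i_squared": res.het.i_squared if res.het else float("nan"),
                "het_p": res.het.p if res.het else float("nan"),
                "or": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "meta_p": res.p,
                "model": res.model,
                "tau2": res.tau2,
            }
        return pd.DataFrame(cols)


def subgroup_meta(
    table: StudyTable,
    model: str = "additive",
    policy: str = "genotype_first",
    maf_scope: str = "combined",
    harmonize: bool = True,
    p_threshold: float = 0.05,
    i2_threshold: float = 50.0,
    force_random: bool = False,
) -> SubgroupAnalysis:
    """Heterogeneity + pooling within each ancestry group and across all studies.

    Model selection (fixed vs random) is applied per stratum unless
    ``force_random`` pins the random-effects model everywhere.  Groups with
    fewer than 2 usable studies are reported in ``skipped`` rather than
    failing the analysis.
    """
    def _pool(effects):
        if force_random:
            return pool_random_dl(effects)
        return pool_auto(effects, p_threshold, i2_threshold)

    all_effects = build_effects(table, model=model, policy=policy, maf_scope=maf_scope, harmonize=harmonize)
    by_group: dict[str, PooledResult] = {}
    skipped: dict[str, int] = {}
    for group in table.groups:
        group_effects = [e for e in all_effects if e.group == group]
        if len(group_effects) < 2:
            skipped[group] = len(group_effects)
            continue
        by_group[group] = _pool(group_effects)
    overall = _pool(all_effects)
    return SubgroupAnalysis(by_group=by_group, overall=overall, skipped=skipped)
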