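import math
import random

import numpy as np
import pytest
from scipy import stats

from bin1meta import (
    EffectEstimate,
    StudyTable,
    TwoByTwoTable,
    cochran_q,
    i_squared,
    pool_fixed_iv,
    pool_fixed_mh,
    pool_random_dl,
    select_model,
    subgroup_meta,
    z_test,
)
from bin1meta.errors import InsufficientStudiesError


def eff(ln_or, se, label="x", group="caucasian"):
    return EffectEstimate(label=label, group=group, ln_or=ln_or, se=se, source="summary_ci")


class TestCochranQ:
    def test_no_dispersion(self):
        het = cochran_q([eff(0.3, 0.1), eff(0.3, 0.2)])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.p == pytest.approx(1.0)
        assert het.i_squared == 0.0

    def test_two_unit_variance_effects(self):
        het = cochran_q([eff(0.0, 1.0), eff(2.0, 1.0)])
        assert het.q == pytest.approx(2.0)
        assert het.df == 1
        assert het.p == pytest.approx(stats.chi2.sf(2.0, 1))  # 0.15729...

    def test_single_study_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([eff(0.1, 0.1)])

    def test_against_brute_force(self):
        # naive loop implementation as the independent oracle
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(2, 12))
            theta = rng.normal(0, 0.5, k)
            se = rng.uniform(0.05, 0.8, k)
            effects = [eff(t, s) for t, s in zip(theta, se)]
            w = [1.0 / s**2 for s in se]
            mu = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
            q_naive = sum(wi * (ti - mu) ** 2 for wi, ti in zip(w, theta))
            het = cochran_q(effects)
            assert het.q == pytest.approx(q_naive, rel=1e-10)
            assert het.i_squared == pytest.approx(
                max(0.0, (q_naive - (k - 1)) / q_naive * 100.0) if q_naive > 0 else 0.0, abs=1e-8
            )


class TestISquared:
    @pytest.mark.parametrize(
        "q, k, expected",
        [
            (10.0, 11, 0.0),  # Q = df boundary
            (20.0, 11, 50.0),  # Q = 2 df
            (28.653, 11, (28.653 - 10) / 28.653 * 100),  # 65.0996...
            (0.0, 5, 0.0),
            (1.0, 30, 0.0),  # clamped below
        ],
    )
    def test_formula_and_clamping(self, q, k, expected):
        assert i_squared(q, k) == pytest.approx(expected)

    def test_bounded(self):
        assert 0.0 <= i_squared(1e9, 2) <= 100.0


class TestFixedIV:
    def test_single_study_passthrough(self):
        e = eff(0.25, 0.12)
        pooled = pool_fixed_iv([e])
        assert pooled.ln_or == pytest.approx(0.25)
        assert pooled.se == pytest.approx(0.12)

    def test_equal_weight_mean(self):
        pooled = pool_fixed_iv([eff(0.1, 0.1), eff(0.3, 0.1)])
        assert pooled.ln_or == pytest.approx(0.2)
        assert pooled.se == pytest.approx(0.1 / math.sqrt(2))  # 0.070711

    def test_precision_accumulates(self, additive_effects):
        pooled = pool_fixed_iv(additive_effects)
        assert pooled.se < min(e.se for e in additive_effects)
        assert sum(pooled.weights) == pytest.approx(1.0, abs=1e-12)


class TestMantelHaenszel:
    def test_single_symmetric_table(self):
        pooled = pool_fixed_mh([TwoByTwoTable(40, 40, 40, 40)])
        assert pooled.odds_ratio == pytest.approx(1.0)

    def test_single_table_equals_table_or(self):
        t = TwoByTwoTable(12, 5, 7, 9)
        pooled = pool_fixed_mh([t])
        assert pooled.odds_ratio == pytest.approx(t.odds_ratio)

    def test_replication_invariance(self):
        t = TwoByTwoTable(12, 5, 7, 9)
        assert pool_fixed_mh([t, t]).odds_ratio == pytest.approx(t.odds_ratio)

    def test_two_table_arithmetic(self):
        tables = [TwoByTwoTable(10, 5, 4, 8), TwoByTwoTable(6, 6, 3, 9)]
        expected = (10 * 8 / 27 + 6 * 9 / 24) / (5 * 4 / 27 + 6 * 3 / 24)  # 3.4969...
        assert pool_fixed_mh(tables).odds_ratio == pytest.approx(expected)

    def test_rbg_variance_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(3)
        cells = rng.integers(5, 200, size=(6, 4))
        tables = [TwoByTwoTable(*row) for row in cells]
        st_table = StratifiedTable([np.array([[t.a, t.b], [t.c, t.d]]) for t in tables])
        pooled = pool_fixed_mh(tables)
        assert pooled.odds_ratio == pytest.approx(st_table.oddsratio_pooled, rel=1e-10)
        assert pooled.se == pytest.approx(st_table.logodds_pooled_se, rel=1e-8)

    def test_agrees_with_iv_on_large_homogeneous_tables(self):
        rng = np.random.default_rng(11)
        tables, effects = [], []
        for _ in range(8):
            n = int(rng.integers(500, 2000))
            t = TwoByTwoTable(0.3 * n, 0.7 * n, 0.25 * n, 0.75 * n)
            tables.append(t)
            from bin1meta import effect_from_table

            effects.append(effect_from_table(t))
        mh = pool_fixed_mh(tables)
        iv = pool_fixed_iv(effects)
        assert mh.odds_ratio == pytest.approx(iv.odds_ratio, rel=0.02)


class TestRandomDL:
    def test_reduces_to_fixed_when_homogeneous(self):
        effects = [eff(0.2, 0.3), eff(0.21, 0.31), eff(0.19, 0.29)]
        dl = pool_random_dl(effects)
        iv = pool_fixed_iv(effects)
        assert dl.tau2 == 0.0
        assert dl.ln_or == pytest.approx(iv.ln_or)
        assert dl.se == pytest.approx(iv.se)

    def test_random_se_never_below_fixed(self, additive_effects):
        dl = pool_random_dl(additive_effects)
        iv = pool_fixed_iv(additive_effects)
        assert dl.se >= iv.se
        assert dl.tau2 > 0.0

    def test_permutation_invariance(self, additive_effects):
        shuffled = list(additive_effects)
        random.Random(5).shuffle(shuffled)
        assert pool_random_dl(shuffled).ln_or == pytest.approx(
            pool_random_dl(additive_effects).ln_or, abs=1e-12
        )

    def test_ci_matches_invariants(self, additive_effects):
        dl = pool_random_dl(additive_effects)
        assert dl.ci_low == pytest.approx(math.exp(dl.ln_or - 1.959964 * dl.se))
        assert dl.ci_high == pytest.approx(math.exp(dl.ln_or + 1.959964 * dl.se))
        assert sum(dl.weights) == pytest.approx(1.0, abs=1e-12)


class TestZTest:
    def test_null(self):
        assert z_test(0.0, 0.5) == (0.0, pytest.approx(1.0))

    def test_quantile_identity(self):
        z, p = z_test(1.959964 * 0.07, 0.07)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_small_p_not_truncated(self):
        _, p = z_test(1.0, 0.05)  # z = 20
        assert 0.0 < p < 1e-80


class TestSelectModel:
    @pytest.mark.parametrize(
        "p, i2, expected",
        [
            (0.001, 65.1, "random_dl"),
            (0.5, 0.0, "fixed"),
            (0.01, 40.0, "fixed"),  # AND rule: significant p alone is not enough
            (0.2, 80.0, "fixed"),
        ],
    )
    def test_rule_table(self, p, i2, expected):
        from bin1meta import HeterogeneityResult

        het = HeterogeneityResult(q=10, df=5, p=p, i_squared=i2)
        assert select_model(het) == expected
        # the looser declaration flag is carried alongside
        assert het.significant_or == (p < 0.05 or i2 > 50)


class TestSubgroupMeta:
    def test_single_group_equals_plain_pooling(self, roster):
        ea = roster.subset("east_asian")
        sub = subgroup_meta(ea, force_random=True)
        assert sub.by_group["east_asian"].ln_or == pytest.approx(sub.overall.ln_or)

    def test_duplicated_groups_are_symmetric(self, roster):
        from bin1meta import StudyRecord

        ea = roster.subset("east_asian")
        clones = [
            StudyRecord(label=r.label, group="caucasian", n_case=r.n_case, n_control=r.n_control,
                        maf=r.maf, or_reported=r.or_reported, or_allele=r.or_allele)
            for r in ea
        ]
        doubled = StudyTable(list(ea.records) + clones)
        sub = subgroup_meta(doubled, force_random=True)
        assert sub.by_group["east_asian"].ln_or == pytest.approx(sub.by_group["caucasian"].ln_or)

    def test_small_group_reported_not_fatal(self, roster):
        small = StudyTable(list(roster.subset("caucasian").records) + [roster.subset("east_asian").records[0]])
        sub = subgroup_meta(small, force_random=True)
        assert sub.skipped == {"east_asian": 1}
        assert "caucasian" in sub.by_group

    def test_model_selection_applied_per_group(self, roster):
        sub = subgroup_meta(roster)  # no force_random: rule decides
        for res in (*sub.by_group.values(), sub.overall):
            expected = "random_dl" if (res.het.p < 0.05 and res.het.i_squared > 50) else "fixed_iv"
            assert res.model == expected
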