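"""Factorial ANOVA, two-sample tests, exact 2x2 tests, rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as strat

from emoprofile import (
    barnard_exact,
    bonferroni_pairwise,
    fisher_exact,
    one_way_anova,
    spearman_rho,
    two_way_anova,
    variance_f_test,
    welch_t,
)


def random_2x3(rng, unbalanced=True):
    ns = rng.integers(5, 20, size=6) if unbalanced else np.full(6, 10)
    a, b, y = [], [], []
    for (la, lb), n in zip(itertools.product("XY", "PQR"), ns):
        a += [la] * n
        b += [lb] * n
        y += list(rng.normal(rng.normal(0, 1), 1.0, size=n))
    return np.array(y), np.array(a), np.array(b)


def statsmodels_type3(y, a, b) -> pd.DataFrame:
    """Independent oracle: statsmodels Type III ANOVA with Sum coding."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "a": a, "b": b})
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    return sm.stats.anova_lm(model, typ=3)


class TestTwoWayAnova:
    def test_translation_invariance(self, rng):
        y, a, b = random_2x3(rng)
        t1 = two_way_anova(y, a, b)
        t2 = two_way_anova(y + 123.4, a, b)
        np.testing.assert_allclose(t1["F"][:3], t2["F"][:3])

    def test_effect_ss_vanishes_without_effects(self, rng):
        a = np.repeat(["X", "Y"], 30)
        b = np.tile(np.repeat(["P", "Q", "R"], 10), 2)
        y = rng.normal(5, 1e-6, size=60)
        tab = two_way_anova(y, a, b)
        assert (tab.loc[["factor_a", "factor_b", "interaction"], "sum_sq"] < 1e-9).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_type3(self, seed):
        """Type III SS / F / p agree with the statsmodels projection
        oracle on random unbalanced 2x3 data."""
        rng = np.random.default_rng(seed)
        y, a, b = random_2x3(rng)
        mine = two_way_anova(y, a, b)
        ref = statsmodels_type3(y, a, b)
        np.testing.assert_allclose(
            mine.loc["factor_a", ["sum_sq", "F", "p"]].astype(float),
            ref.loc["C(a, Sum)", ["sum_sq", "F", "PR(>F)"]].astype(float),
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            mine.loc["factor_b", ["sum_sq", "F", "p"]].astype(float),
            ref.loc["C(b, Sum)", ["sum_sq", "F", "PR(>F)"]].astype(float),
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            mine.loc["interaction", ["sum_sq", "F", "p"]].astype(float),
            ref.loc["C(a, Sum):C(b, Sum)", ["sum_sq", "F", "PR(>F)"]].astype(float),
            rtol=1e-8,
        )

    def test_df_sum_to_n_minus_1(self, rng):
        y, a, b = random_2x3(rng)
        tab = two_way_anova(y, a, b)
        assert tab["df"].sum() == len(y) - 1

    def test_empty_cell_rejected(self, rng):
        y, a, b = random_2x3(rng)
        keep = ~((a == "X") & (b == "P"))
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(y[keep], a[keep], b[keep])


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 15)
        tab = one_way_anova(np.r_[x, y], np.r_[["g1"] * 12, ["g2"] * 15])
        t = st.ttest_ind(x, y, equal_var=True)
        assert tab.loc["factor", "F"] == pytest.approx(t.statistic**2)
        assert tab.loc["factor", "p"] == pytest.approx(t.pvalue)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1.2)]
        tab = one_way_anova(np.concatenate(groups), np.repeat(list("abc"), 10))
        ref = st.f_oneway(*groups)
        assert tab.loc["factor", "F"] == pytest.approx(ref.statistic)
        assert tab.loc["factor", "p"] == pytest.approx(ref.pvalue)


class TestWelchAndVariance:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        r1, r2 = welch_t(x, y), welch_t(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_hand_computed_welch(self):
        """Small fixed vectors against the explicit Welch-Satterthwaite
        formula."""
        x = np.array([10.0, 12.0, 9.0, 11.0])
        y = np.array([14.0, 18.0, 16.0, 20.0, 17.0])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        res = welch_t(x, y)
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == pytest.approx(df_hand)
        assert res.p_raw == pytest.approx(2 * st.t.sf(abs(t_hand), df_hand))

    def test_variance_f_equal_variances(self, rng):
        x = rng.normal(0, 1, 18)
        y = rng.permutation(x) + 5.0  # same spread, shifted
        res = variance_f_test(x, y)
        assert res.F == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_variance_f_printed_anchor(self):
        """F = 5.57 at (17, 17) df gives two-sided p = 0.0009."""
        p = 2 * min(st.f.cdf(5.57, 17, 17), st.f.sf(5.57, 17, 17))
        assert p == pytest.approx(9e-4, abs=5e-5)
        # the same arithmetic must come out of the implementation
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 18)
        y = rng.normal(0, 1, 18)
        res = variance_f_test(x, y)
        ref = 2 * min(st.f.cdf(res.F, 17, 17), st.f.sf(res.F, 17, 17))
        assert res.p_two_sided == pytest.approx(ref)

    @pytest.mark.parametrize("seed", range(8))
    def test_variance_p_matches_integrated_density(self, seed):
        """Two-sided p equals the numerically integrated F-density mass of
        the two tails."""
        from scipy.integrate import quad

        rng = np.random.default_rng(seed)
        x = rng.normal(0, rng.uniform(0.5, 2), rng.integers(5, 25))
        y = rng.normal(0, rng.uniform(0.5, 2), rng.integers(5, 25))
        res = variance_f_test(x, y)
        lower, _ = quad(lambda f: st.f.pdf(f, res.df1, res.df2), 0, res.F)
        oracle = 2 * min(lower, 1 - lower)
        assert res.p_two_sided == pytest.approx(min(1.0, oracle), abs=1e-6)


class TestBonferroniPairwise:
    @staticmethod
    def make_df(rng, sal_sd=(1, 1, 1), vpa_sd=(1, 1, 1), vpa_shift=(0, 0, 0), n=18):
        rows = []
        for i, env in enumerate(("ST", "UE", "PE")):
            for pren, sd, shift in (("SAL", sal_sd[i], 0), ("VPA", vpa_sd[i], vpa_shift[i])):
                for v in rng.normal(shift, sd, n):
                    rows.append(dict(prenatal=pren, environment=env, value=v))
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_1(self, rng):
        df = self.make_df(rng)
        for env in ("ST", "UE", "PE"):
            mask = (df.environment == env) & (df.prenatal == "SAL")
            df.loc[(df.environment == env) & (df.prenatal == "VPA"), "value"] = df.loc[
                mask, "value"
            ].to_numpy()
        results = bonferroni_pairwise(df, "value")
        for res in results:
            assert res.statistic == pytest.approx(0.0)
            assert res.p_adjusted == pytest.approx(1.0)

    def test_welch_triggered_only_by_variance_ratio(self, rng):
        """A 5-fold sd (25-fold variance) ratio in one environment flips
        that comparison, and only that one, to Welch."""
        df = self.make_df(rng, vpa_sd=(1, 5, 1))
        results = {r.group_a.split("-")[1]: r for r in bonferroni_pairwise(df, "value")}
        assert results["UE"].welch_applied
        assert not results["ST"].welch_applied
        assert not results["PE"].welch_applied

    def test_bonferroni_multiplier(self, rng):
        df = self.make_df(rng, vpa_shift=(0.8, 0.8, 0.8))
        for res in bonferroni_pairwise(df, "value"):
            assert res.p_adjusted == pytest.approx(min(1.0, 3 * res.p_raw))
            assert res.p_adjusted >= res.p_raw

    def test_small_group_skipped_with_warning(self, rng):
        df = self.make_df(rng)
        df = df[~((df.environment == "PE") & (df.prenatal == "VPA"))]
        one = df[(df.environment == "PE") & (df.prenatal == "SAL")].iloc[:1].copy()
        one["prenatal"] = "VPA"
        df = pd.concat([df, one])
        with pytest.warns(UserWarning, match="skipped"):
            results = bonferroni_pairwise(df, "value")
        assert len(results) == 2


def enumerate_fisher_p(table) -> float:
    """Full-enumeration oracle for the two-sided minimum-likelihood rule."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = st.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = st.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestFisherExact:
    def test_printed_perseveration_table(self):
        """VPA 10/53 vs SAL 2/54 perseveration: two-tailed p = 0.015."""
        res = fisher_exact([[10, 43], [2, 52]])
        assert res.p_two_sided == pytest.approx(0.015, abs=5e-4)

    def test_identical_rows(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_two_sided == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="margin"):
            assert fisher_exact([[0, 10], [0, 12]]).p_two_sided == 1.0

    @pytest.mark.parametrize("n1,n2", [(5, 7), (8, 8), (12, 9)])
    def test_matches_enumeration_oracle(self, n1, n2):
        for a in range(0, n1 + 1, 2):
            for c in range(0, n2 + 1, 3):
                table = [[a, n1 - a], [c, n2 - c]]
                if min(np.array(table).sum(axis=0)) == 0:
                    continue
                res = fisher_exact(table)
                assert res.p_two_sided == pytest.approx(
                    enumerate_fisher_p(table), abs=1e-10
                ), table

    @given(
        a=strat.integers(0, 12), b=strat.integers(0, 12),
        c=strat.integers(0, 12), d=strat.integers(0, 12),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_swap_invariance(self, a, b, c, d):
        """Simultaneously swapping both rows and both columns leaves p
        unchanged."""
        t1 = [[a, b], [c, d]]
        t2 = [[d, c], [b, a]]
        assert fisher_exact(t1).p_two_sided == pytest.approx(
            fisher_exact(t2).p_two_sided, abs=1e-12
        )


def brute_force_barnard(table, grid_step=1e-4):
    """Dense-grid brute-force oracle for the Wald-score unconditional test."""
    (x1, f1), (x2, f2) = table
    n1, n2 = x1 + f1, x2 + f2
    T = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            pp = (i + j) / (n1 + n2)
            var = pp * (1 - pp) * (1 / n1 + 1 / n2)
            T[i, j] = (i / n1 - j / n2) / np.sqrt(var) if var > 0 else 0.0
    extreme = np.abs(T) >= abs(T[x1, x2]) - 1e-12
    best = 0.0
    for pi in np.arange(grid_step, 1.0, grid_step):
        p1 = st.binom.pmf(np.arange(n1 + 1), n1, pi)
        p2 = st.binom.pmf(np.arange(n2 + 1), n2, pi)
        best = max(best, float(np.outer(p1, p2)[extreme].sum()))
    return min(1.0, best)


class TestBarnardExact:
    def test_equal_proportions_give_p_1(self):
        res = barnard_exact([[6, 12], [6, 12]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_dense_grid_oracle(self):
        """Matches a step-1e-4 brute-force supremum to 3 decimals."""
        table = [[3, 15], [0, 18]]
        res = barnard_exact(table)
        assert res.p_two_sided == pytest.approx(
            brute_force_barnard(table), abs=5e-4
        )

    def test_matches_scipy_unconditional(self):
        """Cross-check against scipy's independent implementation of the
        pooled-score unconditional test (scipy tables are transposed:
        columns are the two groups)."""
        for table in ([[3, 15], [0, 18]], [[5, 13], [1, 17]], [[4, 13], [1, 16]]):
            res = barnard_exact(table)
            t = np.array(table)
            ref = st.barnard_exact(t.T, pooled=True)
            assert abs(res.statistic) == pytest.approx(abs(ref.statistic), abs=1e-9)
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=2e-3)

    def test_contract_p_in_unit_interval_and_pi_sup(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(4, 15, 2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            res = barnard_exact([[x1, n1 - x1], [x2, n2 - x2]])
            assert 0 <= res.p_two_sided <= 1
            if not np.isnan(res.pi_sup):
                assert 0 < res.pi_sup < 1

    def test_all_zero_successes(self):
        res = barnard_exact([[0, 10], [0, 12]])
        assert res.statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_swap_invariance(self):
        t1 = [[4, 14], [1, 17]]
        t2 = [[17, 1], [14, 4]]
        assert barnard_exact(t1).p_two_sided == pytest.approx(
            barnard_exact(t2).p_two_sided, abs=1e-9
        )


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x * 3 + 1)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -(x**2))[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson(self):
        """Mean-rank tie handling: rank explicitly, then Pearson."""
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        rho, _ = spearman_rho(x, y)
        oracle = np.corrcoef(st.rankdata(x), st.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle)

    def test_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.0, 5.0, np.nan, 9.0, 12.0])
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
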