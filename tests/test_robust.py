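"""Robust statistical battery: trimmed means, factorial test, contrasts,
exact WMW, chi-square uniformity, power, gates."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from judoba.robust import (
    PowerQuery,
    anova_power,
    chisq_axis_uniformity,
    distribution_gates,
    exact_u_counts,
    pairwise_trimmed_contrasts,
    required_group_n,
    robust_two_way,
    rosenthal_r,
    trimmed_mean,
    winsorized_variance,
    wmw_exact_z,
    yuen,
)


class TestTrimmedPrimitives:
    def test_trimmed_mean_known_case(self):
        assert trimmed_mean(range(1, 11), trim=0.2) == 5.5  # mean of 3..8

    def test_trim_zero_is_arithmetic(self, rng):
        x = rng.normal(size=25)
        assert trimmed_mean(x, 0.0) == pytest.approx(x.mean())
        assert winsorized_variance(x, 0.0) == pytest.approx(x.var(ddof=1))

    def test_matches_sort_and_slice_oracle(self, rng):
        # brute-force oracle: sort, slice / clamp explicitly
        for _ in range(200):
            n = int(rng.integers(5, 40))
            trim = float(rng.uniform(0, 0.45))
            x = rng.normal(size=n) * rng.uniform(0.1, 10)
            g = math.floor(trim * n)
            xs = np.sort(x)
            assert trimmed_mean(x, trim) == pytest.approx(xs[g : n - g].mean())
            w = np.concatenate([[xs[g]] * g, xs[g : n - g], [xs[n - g - 1]] * g])
            assert winsorized_variance(x, trim) == pytest.approx(w.var(ddof=1))

    def test_empty_or_overtrimmed_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([], 0.2)  # nothing left to average
        with pytest.raises(ValueError):
            trimmed_mean([1.0, 2.0], 0.5)  # trim must stay below 0.5


class TestRobustTwoWay:
    @staticmethod
    def null_cells(rng, n=16):
        return {(s, w): rng.normal(0, 1, n) for s in (0, 1) for w in (0, 1, 2)}

    def test_constant_identical_cells(self):
        cells = {(s, w): np.full(10, 3.14) for s in (0, 1) for w in (0, 1, 2)}
        res = robust_two_way(cells)
        assert res.q_sex == res.q_weight == res.q_interaction == 0.0
        assert res.p_sex == res.p_weight == res.p_interaction == 1.0

    def test_invariant_to_level_relabelling(self, rng):
        cells = self.null_cells(rng)
        res = robust_two_way(cells)
        relabelled = {("z" + str(s), "y" + str((w + 1) % 3)): v
                      for (s, w), v in cells.items()}
        res2 = robust_two_way(relabelled)
        assert res2.p_sex == pytest.approx(res.p_sex)
        assert res2.p_weight == pytest.approx(res.p_weight)
        assert res2.p_interaction == pytest.approx(res.p_interaction)

    def test_empty_cell_named(self, rng):
        cells = self.null_cells(rng)
        cells[(0, 2)] = np.array([])
        with pytest.raises(ValueError, match=r"\(0, 2\)"):
            robust_two_way(cells)

    def test_strong_interaction_detected(self, rng):
        cells = self.null_cells(rng)
        cells[(0, 0)] = cells[(0, 0)] + 10.0  # one cell shifted: interaction
        res = robust_two_way(cells)
        assert res.p_interaction < 0.001

    def test_trim0_agrees_with_classical_anova_on_clean_data(self):
        # On balanced homoscedastic normal data the untrimmed Johansen
        # test should track the classical two-way F-test closely.
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(21)
        p_rob, p_cls = [], []
        for _ in range(200):
            cells = {(s, w): rng.normal(0, 1, 20) for s in (0, 1) for w in (0, 1, 2)}
            res = robust_two_way(cells, trim=0.0)
            rows = [
                {"y": y, "a": s, "b": w}
                for (s, w), v in cells.items()
                for y in v
            ]
            df = pd.DataFrame(rows)
            fit = ols("y ~ C(a) * C(b)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            p_rob.append(res.p_interaction)
            p_cls.append(tab.loc["C(a):C(b)", "PR(>F)"])
        p_rob, p_cls = np.array(p_rob), np.array(p_cls)
        assert np.corrcoef(p_rob, p_cls)[0, 1] > 0.98
        assert abs((p_rob < 0.05).mean() - (p_cls < 0.05).mean()) <= 0.03


class TestPairwiseContrasts:
    def test_identical_cells_nothing_significant(self):
        cells = {lab: np.arange(16.0) for lab in "ABCDEF"}
        cons = pairwise_trimmed_contrasts(cells)
        assert len(cons) == 15
        assert not any(c.significant for c in cons)

    def test_forced_separation_significant(self, rng):
        cells = {lab: rng.normal(0, 1, 16) for lab in "ABCDEF"}
        cells["F"] = cells["F"] + 10.0  # 10 pooled SDs away
        cons = pairwise_trimmed_contrasts(cells)
        af = next(c for c in cons if {c.cell_a, c.cell_b} == {"A", "F"})
        assert af.significant and af.p < 0.001

    def test_hochberg_no_less_powerful_than_smm_here(self, rng):
        cells = {lab: rng.normal(i * 0.8, 1, 16) for i, lab in enumerate("ABCDEF")}
        smm = pairwise_trimmed_contrasts(cells, method="smm")
        hoch = pairwise_trimmed_contrasts(cells, method="hochberg")
        assert len(smm) == len(hoch) == 15
        for c in hoch:
            assert 0.0 <= c.p <= 1.0


class TestExactWMW:
    def test_counts_match_full_enumeration_5_5(self):
        # every one of the C(10,5)=252 rank splits, counted directly
        counts = exact_u_counts(5, 5)
        brute = np.zeros(26)
        ranks = range(10)
        for subset in itertools.combinations(ranks, 5):
            rest = [r for r in ranks if r not in subset]
            u = sum(1 for a in subset for b in rest if a > b)
            brute[u] += 1
        assert counts.sum() == 252
        assert np.array_equal(counts, brute)

    def test_two_sided_p_matches_scipy_exact(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, int(rng.integers(4, 12)))
            b = rng.normal(0.8, 1, int(rng.integers(4, 12)))
            z = wmw_exact_z(a, b)
            p_mine = 2 * stats.norm.sf(abs(z)) if z != 0 else 1.0
            p_scipy = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert p_mine == pytest.approx(min(1.0, p_scipy), abs=1e-9)

    def test_sign_convention(self):
        a = np.arange(10, 20.0)
        b = np.arange(0, 10.0)
        assert wmw_exact_z(a, b) > 0  # a stochastically dominates
        assert wmw_exact_z(b, a) < 0

    def test_all_tied_gives_zero(self):
        assert wmw_exact_z([1.0] * 5, [1.0] * 5) == 0.0

    def test_exact_close_to_normal_approximation_at_n30(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        z = wmw_exact_z(a, b)
        p_exact = 2 * stats.norm.sf(abs(z))
        # force the approximation branch by exceeding the exact-size cap
        import judoba.robust as rb
        old = rb.EXACT_WMW_MAX_N
        try:
            rb.EXACT_WMW_MAX_N = 0
            z_n = wmw_exact_z(a, b)
        finally:
            rb.EXACT_WMW_MAX_N = old
        p_norm = 2 * stats.norm.sf(abs(z_n))
        assert abs(p_exact - p_norm) < 0.01

    @given(st.floats(-1000, 1000))
    def test_shift_invariance(self, shift):
        a = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        assert wmw_exact_z(a + shift, b + shift) == pytest.approx(wmw_exact_z(a, b))


class TestRosenthalR:
    def test_arithmetic(self):
        r, _ = rosenthal_r(2.0, 16)
        assert r == 0.5

    @pytest.mark.parametrize(
        "r_val, label",
        [(0.1, "below-small"), (0.35, "small"), (0.73, "moderate"), (0.9, "great")],
    )
    def test_magnitude_labels(self, r_val, label):
        # r = Z/sqrt(N): choose Z to land on the desired r at N=16
        r, mag = rosenthal_r(r_val * 4.0, 16)
        assert r == pytest.approx(r_val)
        assert mag == label


class TestChiSquareUniformity:
    def test_uniform_shares(self):
        chi2, p = chisq_axis_uniformity((33.33, 33.33, 33.34))
        assert chi2 == pytest.approx(0.0, abs=1e-3)
        assert p > 0.999

    def test_degenerate_single_axis(self):
        chi2, p = chisq_axis_uniformity((100, 0, 0))
        assert chi2 == pytest.approx(200.0)
        assert p < 1e-40

    def test_permutation_invariance(self):
        base = chisq_axis_uniformity((29.3, 31.1, 39.6))
        for perm in itertools.permutations((29.3, 31.1, 39.6)):
            assert chisq_axis_uniformity(perm) == pytest.approx(base)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chisq_axis_uniformity((0, 0, 0))


class TestPower:
    def test_study_sizing(self):
        n = required_group_n(PowerQuery(k_groups=6, effect_f=0.40,
                                        alpha=0.05, power=0.85))
        assert n == 16

    def test_monotone_in_power(self):
        ns = [
            required_group_n(PowerQuery(6, 0.40, 0.05, p))
            for p in (0.5, 0.7, 0.85, 0.95)
        ]
        assert ns == sorted(ns)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            required_group_n(PowerQuery(6, 0.0, 0.05, 0.85))

    def test_power_matches_monte_carlo_oracle(self):
        # simulate the one-way ANOVA at the returned n and compare the
        # empirical rejection rate with the noncentral-F power
        k, f, alpha, n = 6, 0.40, 0.05, 16
        mus = np.array([-1.0, -0.6, -0.2, 0.2, 0.6, 1.0])
        mus = mus / np.sqrt((mus**2).mean()) * f  # Cohen's f = sd(mu)/sigma
        rng = np.random.default_rng(17)
        reps = 4000
        rej = 0
        for _ in range(reps):
            groups = [rng.normal(m, 1.0, n) for m in mus]
            _, p = stats.f_oneway(*groups)
            rej += p < alpha
        expected = anova_power(n, k, f, alpha)
        se = math.sqrt(expected * (1 - expected) / reps)
        assert abs(rej / reps - expected) < 3 * se + 1e-9


class TestGates:
    def test_constant_sample_untestable(self):
        rep = distribution_gates({"a": [2.0] * 10, "b": [1.0, 2.0, 3.0, 4.0]})
        assert rep.normality["a"] is None
        assert rep.normality["b"] is not None

    def test_heavy_tails_fail_normality(self):
        rng = np.random.default_rng(3)
        samples = {str(i): stats.cauchy.rvs(size=16, random_state=rng)
                   for i in range(60)}
        rep = distribution_gates(samples)
        fails = sum(1 for v in rep.normality.values() if v is not None and v[1] < 0.05)
        assert fails > 30  # heavy tails should fail normality in the majority

    def test_bartlett_null_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(300):
            rep = distribution_gates(
                {str(i): rng.normal(0, 1, 16) for i in range(6)}
            )
            ps.append(rep.bartlett_p)
        # uniform p-values: mean near 0.5, ~5% below 0.05
        assert abs(np.mean(ps) - 0.5) < 0.06
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.04


def test_yuen_matches_welch_when_untrimmed(rng):
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
    t, df, p, diff = yuen(a, b, trim=0.0)
    t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(t_ref)
    assert p == pytest.approx(p_ref)
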