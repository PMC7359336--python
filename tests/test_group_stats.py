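"""t-tests, ANOVA, JZS Bayes factors and the exact r x c Fisher test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from magclass import (
    fisher_exact_rxc,
    jzs_anova_bf,
    jzs_ttest_bf,
    one_sample_t,
    oneway_anova,
    t_from_summary,
    table1_report,
)

value_arrays = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=5, max_size=30,
).filter(lambda v: np.std(v, ddof=1) > 1e-6)


class TestOneSampleT:
    @given(values=value_arrays)
    def test_matches_textbook_formula_oracle(self, values):
        v = np.asarray(values)
        res = one_sample_t(v)
        t_oracle = v.mean() / (v.std(ddof=1) / np.sqrt(v.size))
        assert res.t == pytest.approx(t_oracle, abs=1e-12 * max(1, abs(t_oracle)))
        assert res.df == v.size - 1

    @given(values=value_arrays)
    def test_d_equals_t_over_sqrt_n(self, values):
        res = one_sample_t(np.asarray(values))
        assert res.d == pytest.approx(res.t / np.sqrt(res.n), abs=1e-12)

    def test_symmetric_values_give_t_zero_p_one(self):
        res = one_sample_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_one_sided_tails(self):
        v = [-3.0, -2.0, -2.5, -1.0, -2.2]
        assert one_sample_t(v, alternative="less").p < 0.05
        assert one_sample_t(v, alternative="greater").p > 0.95

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0])

    def test_summary_form_agrees_with_raw_form(self, rng):
        v = rng.normal(3, 2, 40)
        a = one_sample_t(v, alternative="greater")
        b = t_from_summary(v.mean(), v.std(ddof=1), v.size, alternative="greater")
        assert a.t == pytest.approx(b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)
        assert a.d == pytest.approx(b.d, abs=1e-12)


class TestOnewayAnova:
    def test_identical_group_means_give_zero_F(self):
        res = oneway_anova([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.eta_p2 == pytest.approx(0.0, abs=1e-12)

    def test_two_group_F_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        res = oneway_anova(np.concatenate([a, b]), ["a"] * 20 + ["b"] * 25)
        t = stats.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 15) for m in (0, 0.3, 0.6)]
        labels = sum([[g] * 15 for g in "abc"], [])
        res = oneway_anova(np.concatenate(groups), labels)
        ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_eta_identity_with_F_and_dfs(self, rng):
        vals = rng.normal(0, 1, 60)
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        res = oneway_anova(vals, labels)
        eta = res.F * res.df_between / (res.F * res.df_between + res.df_within)
        assert res.eta_p2 == pytest.approx(eta, abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


def bf_quadrature_oracle(t, n, direction="two_sided", n_points=1_000_000):
    """Brute-force trapezoid over the Cauchy-angle substitution."""
    nu = n - 1
    r = np.sqrt(2) / 2
    if direction == "two_sided":
        lo, hi, norm = -np.pi / 2, np.pi / 2, 1 / np.pi
    elif direction == "negative":
        lo, hi, norm = -np.pi / 2, 0, 2 / np.pi
    else:
        lo, hi, norm = 0, np.pi / 2, 2 / np.pi
    # open grid: the integrand vanishes toward tan(+/- pi/2) but evaluates
    # to nan exactly at the poles
    h = (hi - lo) / n_points
    theta = lo + (np.arange(n_points) + 0.5) * h
    dens = stats.nct.pdf(t, nu, r * np.tan(theta) * np.sqrt(n))
    m1 = norm * dens.sum() * h
    return m1 / stats.t.pdf(t, nu)


class TestJZSTTestBF:
    def test_null_t_favours_null(self):
        assert jzs_ttest_bf(0.0, 50) < 1.0

    @pytest.mark.parametrize("t,n,direction", [
        (2.5, 30, "two_sided"),
        (-5.06, 13, "negative"),
        (1.2, 15, "positive"),
    ])
    def test_matches_brute_force_quadrature(self, t, n, direction):
        bf = jzs_ttest_bf(t, n, direction=direction)
        oracle = bf_quadrature_oracle(t, n, direction)
        assert bf == pytest.approx(oracle, rel=1e-4)

    def test_two_sided_is_mean_of_one_sided(self):
        t, n = 2.2, 40
        two = jzs_ttest_bf(t, n)
        lo = jzs_ttest_bf(t, n, direction="negative")
        hi = jzs_ttest_bf(t, n, direction="positive")
        assert two == pytest.approx((lo + hi) / 2, rel=1e-8)

    def test_matches_pingouin_two_sided(self):
        pingouin = pytest.importorskip("pingouin")
        bf = jzs_ttest_bf(3.0, 25)
        ref = float(pingouin.bayesfactor_ttest(3.0, 25, paired=True))
        assert bf == pytest.approx(ref, rel=1e-3)


class TestJZSAnovaBF:
    def test_true_null_favours_null(self, rng):
        vals = rng.normal(0, 1, 200)
        labels = ["a"] * 100 + ["b"] * 100
        assert jzs_anova_bf(vals, labels) < 1.0

    def test_one_sd_shift_gives_strong_evidence(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = ["a"] * 50 + ["b"] * 50
        assert jzs_anova_bf(vals, labels) > 10.0

    def test_location_and_scale_invariance(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        base = jzs_anova_bf(vals, labels)
        assert jzs_anova_bf(vals + 100.0, labels) == pytest.approx(base, rel=1e-6)
        assert jzs_anova_bf(vals * 7.0, labels) == pytest.approx(base, rel=1e-6)


class TestFisherExact:
    @pytest.mark.parametrize("table", [
        [[3, 7], [5, 2]],
        [[10, 2], [4, 9]],
        [[1, 1], [1, 1]],
    ])
    def test_2x2_matches_scipy_oracle(self, table):
        res = fisher_exact_rxc(table)
        _, p_ref = stats.fisher_exact(table)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_proportional_rows_give_p_one(self):
        res = fisher_exact_rxc([[2, 4], [4, 8]])
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_enumerate_and_montecarlo_agree(self, rng):
        table = [[6, 2, 4], [3, 7, 2], [5, 4, 8]]
        exact = fisher_exact_rxc(table, method="enumerate")
        mc = fisher_exact_rxc(table, method="montecarlo", n_mc=200_000, seed=1)
        assert abs(mc.p - exact.p) < 3 * mc.se

    def test_budget_overflow_falls_back_to_montecarlo(self):
        table = [[30, 25, 28], [27, 31, 26], [29, 24, 33]]
        with pytest.warns(RuntimeWarning):
            res = fisher_exact_rxc(table, max_tables=100, n_mc=10_000, seed=2)
        assert res.method == "montecarlo"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -1], [2, 2]])


class TestNullCalibration:
    def test_one_sided_t_rejects_at_five_percent_under_null(self, rng):
        # 5000 cohorts of n=98 null slopes; empirical alpha within 1 point
        sims = rng.normal(0, 1, size=(5000, 98))
        means = sims.mean(axis=1)
        sds = sims.std(axis=1, ddof=1)
        t = means / (sds / np.sqrt(98))
        p = stats.t.cdf(t, df=97)  # one-sided toward negative
        alpha = (p < 0.05).mean()
        assert alpha == pytest.approx(0.05, abs=0.01)


class TestTable1Report:
    def test_populated_report_from_synthetic_cohort(self, realistic_cohort):
        from magclass import classify_cohort, fit_all_participants

        _, _, _, retained, _ = realistic_cohort
        slopes = fit_all_participants(retained)
        cls = classify_cohort(retained, slopes, n_iter=200, seed=0)
        rep = table1_report(slopes, cls)
        assert set(rep["group"]) == {"Overall", "M", "E", "S", "R"}
        assert rep["bf10"].notna().all()
        pct = rep[["reliable_pct", "reliable_reverse_pct", "not_reliable_pct"]]
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)

    def test_single_group_cohort(self, rng):
        import pandas as pd

        slopes = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(10)],
            "group": "A",
            "nde_slope": rng.normal(-10, 4, 10),
            "nse_slope": rng.normal(1, 2, 10),
        })
        cls = pd.DataFrame({
            "participant_id": list(slopes["participant_id"]) * 2,
            "group": "A",
            "effect": ["nde"] * 10 + ["nse"] * 10,
            "label": ["reliable_typical"] * 10 + ["not_reliable"] * 10,
        })
        rep = table1_report(slopes, cls)
        assert set(rep["group"]) == {"Overall", "A"}
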