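import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm

from hemigrad.stats import (
    POSTHOC_ALPHA,
    chi_square_independence,
    fdr_bh,
    hotelling_group_test,
    network_aggregate,
    posthoc_gradient_tests,
    unitwise_group_comparison,
)


class TestFdrBH:
    def test_identical_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.01] * 10), [0.01] * 10)

    def test_matches_stepup_oracle(self):
        q = fdr_bh([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_dominates_p_and_respects_ranks(self, rng):
        p = rng.random(50)
        q = fdr_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestChiSquare:
    def test_cohort_sex_table(self):
        chi2, p = chi_square_independence([[56, 53], [58, 74]])
        assert chi2 == pytest.approx(1.32, abs=0.005)
        assert 0.2 < p < 0.3

    def test_proportional_rows_give_zero(self):
        chi2, _ = chi_square_independence([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_closed_form(self):
        chi2, _ = chi_square_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [5, 5]])


def _design_data(rng, n=60, shift=0.0, p=3):
    group = np.array(["MDD"] * (n // 2) + ["HC"] * (n // 2))
    cov = np.column_stack(
        [rng.uniform(20, 70, n), rng.integers(0, 2, n), rng.uniform(0, 0.3, n)]
    )
    Y = rng.standard_normal((n, p))
    Y[group == "MDD"] += shift
    return Y, group, cov


class TestHotelling:
    def test_reduces_to_squared_t_for_single_response(self, rng):
        Y, group, cov = _design_data(rng, p=1)
        res = hotelling_group_test(Y, group, cov)
        ph = posthoc_gradient_tests(Y, group, cov)[0]
        assert res.t2 == pytest.approx(ph.t**2, abs=1e-10)
        assert res.df1 == 1

    def test_strong_shift_detected(self, rng):
        ps = []
        for _ in range(5):
            Y, group, cov = _design_data(rng, n=100, shift=1.0)
            ps.append(hotelling_group_test(Y, group, cov).p)
        assert np.median(ps) < 1e-6

    def test_f_transform_consistency(self, rng):
        Y, group, cov = _design_data(rng)
        res = hotelling_group_test(Y, group, cov)
        n, r, p = 60, 5, 3
        expected_f = res.t2 * (n - r - p + 1) / (p * (n - r))
        assert res.f_stat == pytest.approx(expected_f, abs=1e-12)
        assert res.p == pytest.approx(
            scipy.stats.f.sf(expected_f, 3, n - r - 2), abs=1e-12
        )

    def test_singular_design_rejected(self, rng):
        Y, group, _ = _design_data(rng)
        cov = np.column_stack([(np.asarray(group) == "MDD").astype(float)])
        with pytest.raises(ValueError, match="singular"):
            hotelling_group_test(Y, group, cov)

    def test_too_few_subjects_rejected(self, rng):
        Y, group, cov = _design_data(rng, n=8)
        with pytest.raises(ValueError, match="few"):
            hotelling_group_test(Y, group, cov)


class TestPosthoc:
    def test_matches_statsmodels_ols(self, rng):
        Y, group, cov = _design_data(rng, n=8)
        results = posthoc_gradient_tests(Y, group, None)
        X = sm.add_constant((np.asarray(group) == "MDD").astype(float))
        for k, res in enumerate(results):
            fit = sm.OLS(Y[:, k], X).fit()
            assert res.t == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_significance_threshold_is_bonferroni_three(self, rng):
        Y, group, cov = _design_data(rng, n=200, shift=0.8)
        results = posthoc_gradient_tests(Y, group, cov)
        for res in results:
            assert res.significant == (res.p < POSTHOC_ALPHA)

    def test_selective_recovery_of_planted_gradient(self, rng):
        hits, false = 0, 0
        reps = 100
        for _ in range(reps):
            n = 100
            group = np.array(["MDD"] * 50 + ["HC"] * 50)
            Y = rng.standard_normal((n, 3))
            Y[group == "MDD", 0] += 1.0  # d = 1 on G1 only
            res = posthoc_gradient_tests(Y, group, None)
            hits += res[0].significant
            false += res[1].significant or res[2].significant
        assert hits / reps >= 0.9
        assert false / reps < 0.2

    def test_zero_residual_variance_rejected(self):
        Y = np.zeros((20, 3))
        group = np.array(["MDD"] * 10 + ["HC"] * 10)
        with pytest.raises(ValueError, match="residual variance"):
            posthoc_gradient_tests(Y, group, None)


class TestNetworkAggregate:
    def test_constant_network_passthrough(self):
        stack = np.full((5, 6, 3), 0.7)
        nets = np.array(["A"] * 3 + ["B"] * 3)
        out, order = network_aggregate(stack, nets)
        assert order == ["A", "B"]
        np.testing.assert_allclose(out, 0.7)

    def test_two_pair_mean(self):
        stack = np.zeros((1, 2, 1))
        stack[0, 0, 0], stack[0, 1, 0] = 0.1, 0.3
        out, _ = network_aggregate(stack, np.array(["N", "N"]))
        assert out[0, 0, 0] == pytest.approx(0.2)

    def test_matches_groupby_oracle(self, rng):
        stack = rng.standard_normal((7, 12, 3))
        nets = rng.choice(["A", "B", "C"], 12)
        out, order = network_aggregate(stack, nets)
        for j, lab in enumerate(order):
            np.testing.assert_allclose(
                out[:, j, :], stack[:, nets == lab, :].mean(axis=1)
            )

    def test_label_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            network_aggregate(rng.standard_normal((3, 5, 3)), np.array(["A"] * 4))


class TestUnitwise:
    def test_q_values_and_flags(self, rng):
        stack = rng.standard_normal((80, 10, 3))
        group = np.array(["MDD"] * 40 + ["HC"] * 40)
        stack[group == "MDD", 0, :] += 1.0
        mv, ph = unitwise_group_comparison(stack, group, None)
        assert len(mv) == 10
        assert mv.loc[0, "q"] < 0.05 and mv.loc[0, "significant"]
        np.testing.assert_allclose(mv["q"], fdr_bh(mv["p"].to_numpy()))
        assert len(ph) == 30
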