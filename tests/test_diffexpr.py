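import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncnet import (
    ModerationPrior,
    fit_moderation_prior,
    log2_fold_change,
    mann_whitney,
    moderated_t_test,
    paired_t,
    welch_t_test,
)
from lncnet.containers import ValidationError
from lncnet.diffexpr import DesignError, pooled_variance

from conftest import make_matrix


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "case_mean, control_mean, log2fc, fc",
        [(3.0, 2.0, 1.0, 2.0), (2.0, 2.0, 0.0, 1.0), (1.0, 2.0, -1.0, -2.0)],
    )
    def test_worked_examples(self, case_mean, control_mean, log2fc, fc):
        values = np.array([[case_mean] * 2 + [control_mean] * 2])
        out = log2_fold_change(make_matrix(values, n_case=2))
        assert out["log2fc"].iloc[0] == pytest.approx(log2fc)
        assert out["fc"].iloc[0] == pytest.approx(fc)

    def test_symmetric_fc_magnitude(self, rng):
        values = rng.normal(8, 1, size=(20, 10))
        m1 = make_matrix(values, n_case=5)
        m2 = make_matrix(values[:, ::-1], n_case=5)  # swap the groups
        f1, f2 = log2_fold_change(m1), log2_fold_change(m2)
        np.testing.assert_allclose(f1["log2fc"], -f2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(np.abs(f1["fc"]), np.abs(f2["fc"]), atol=1e-12)


class TestModerationPrior:
    def test_constant_variance_gives_infinite_d0(self):
        # zero dispersion of log variances -> no heterogeneity detectable;
        # s0_sq is the bias-adjusted geometric mean, exp(mean(log s2) +
        # log(d/2) - digamma(d/2)), the chi-square log-scale correction
        from scipy.special import digamma

        d = 20
        s2 = np.full(100, 0.25)
        prior = fit_moderation_prior(s2, d)
        assert math.isinf(prior.d0)
        expected = 0.25 * math.exp(math.log(d / 2) - digamma(d / 2))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_homogeneous_chi2_variances_give_large_d0(self, rng):
        # s^2 ~ s0^2 * chi2_d / d with no between-probe component
        d, s0_sq = 20, 0.25
        s2 = s0_sq * rng.chisquare(d, size=5000) / d
        prior = fit_moderation_prior(s2, d)
        assert math.isinf(prior.d0) or prior.d0 > 50
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_scaled_f_mixture_recovers_d0(self, rng):
        # true per-probe variances from a scaled inverse chi-square, d0=4
        d, d0, s0_sq = 20, 4.0, 0.25
        n = 5000
        true_var = s0_sq * d0 / rng.chisquare(d0, size=n)
        s2 = true_var * rng.chisquare(d, size=n) / d
        prior = fit_moderation_prior(s2, d)
        assert 2.5 <= prior.d0 <= 6
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.25)

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(ValidationError, match="zero"):
            fit_moderation_prior(np.zeros(100), 20)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValidationError, match="30"):
            fit_moderation_prior(np.full(10, 0.3), 20)


class TestModeratedT:
    def test_d0_zero_reproduces_ordinary_pooled_t(self, two_group_matrix):
        prior = ModerationPrior(d0=0.0, s0_sq=1.0)
        out = moderated_t_test(two_group_matrix, prior)
        case = two_group_matrix.values[two_group_matrix.case_ids].to_numpy()
        control = two_group_matrix.values[two_group_matrix.control_ids].to_numpy()
        ref = stats.ttest_ind(case, control, axis=1, equal_var=True)
        np.testing.assert_allclose(out["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(out["p_value"], ref.pvalue, atol=1e-10)

    def test_d0_infinite_uses_prior_variance_exactly(self, two_group_matrix):
        s0_sq = 0.37
        prior = ModerationPrior(d0=math.inf, s0_sq=s0_sq)
        out = moderated_t_test(two_group_matrix, prior)
        fc = log2_fold_change(two_group_matrix)["log2fc"]
        n1, n2 = 13, 9
        expected = fc / math.sqrt(s0_sq * (1 / n1 + 1 / n2))
        np.testing.assert_allclose(out["t"], expected, atol=1e-12)

    def test_hand_evaluated_posterior_variance_formula(self):
        # 13 case values at 3, 9 controls at 2, with a deterministic jitter so
        # the sample variance is positive; prior (d0=4, s0_sq=0.25)
        jitter = 0.01 * np.arange(22)
        values = (np.array([3.0] * 13 + [2.0] * 9) + jitter)[None, :]
        matrix = make_matrix(values, n_case=13)
        d0, s0_sq = 4.0, 0.25
        out = moderated_t_test(matrix, ModerationPrior(d0, s0_sq))

        case, control = values[0, :13], values[0, 13:]
        d = 20
        s2 = (case.var(ddof=1) * 12 + control.var(ddof=1) * 8) / d
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        t_expected = (case.mean() - control.mean()) / math.sqrt(
            s2_post * (1 / 13 + 1 / 9)
        )
        assert out["t"].iloc[0] == pytest.approx(t_expected, abs=1e-12)
        assert out["df_total"].iloc[0] == pytest.approx(d + d0)
        p_expected = 2 * stats.t.sf(abs(t_expected), d + d0)
        assert out["p_value"].iloc[0] == pytest.approx(p_expected, abs=1e-12)

    def test_monotone_in_fold_change_at_fixed_variance(self):
        # same within-group scatter, increasing mean shifts -> |t| increases
        base = np.tile(np.array([0.1, -0.1, 0.0, 0.2, -0.2, 0.0] * 2), (4, 1))
        shifts = [0.5, 1.0, 1.5, 2.0]
        for i, s in enumerate(shifts):
            base[i, :6] += s
        out = moderated_t_test(
            make_matrix(base, n_case=6), ModerationPrior(4.0, 0.25)
        )
        assert out["t"].is_monotonic_increasing

    def test_is_de_filter_and_fdr(self, two_group_matrix):
        out = moderated_t_test(two_group_matrix)
        on = out["is_de"]
        expected = (out["fc"].abs() >= 1.5) & (out["p_value"] < 0.05)
        assert (on == expected).all()
        assert out["fdr"].between(0, 1).all()

    def test_bh_matches_bruteforce_on_small_input(self, rng):
        values = rng.normal(8, 0.5, size=(8, 10))
        out = moderated_t_test(
            make_matrix(values, n_case=5), ModerationPrior(4.0, 0.25)
        )
        p = out["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running_min = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running_min = min(running_min, p[i] * m / (rank_from_top + 1))
            adj[i] = running_min
        np.testing.assert_allclose(out["fdr"], adj, atol=1e-12)


class TestAlternativeTests:
    def test_welch_calibrated_under_null(self, rng):
        values = rng.normal(0, 1, size=(10_000, 22))
        out = welch_t_test(make_matrix(values, n_case=13))
        rate = (out["p_value"] < 0.05).mean()
        assert 0.04 <= rate <= 0.06

    def test_mann_whitney_exact_worked_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 label arrangements as extreme

    def test_mann_whitney_exact_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(loc=0.8, size=6)
            u, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_mann_whitney_large_n_matches_scipy_asymptotic(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(loc=0.5, size=12)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_mann_whitney_all_ties_undefined(self):
        with pytest.raises(ValidationError):
            mann_whitney([1, 1, 1], [1, 1, 1])

    def test_paired_t_zero_variance_error(self):
        x = [1.0, 2.0, 3.0]
        with pytest.raises(ValidationError):
            paired_t(x, x)

    def test_paired_t_matches_scipy(self, rng):
        before = rng.normal(size=10)
        after = before + rng.normal(0.5, 0.3, size=10)
        t, p = paired_t(before, after)
        ref = stats.ttest_rel(after, before)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_group_too_small_rejected(self):
        with pytest.raises(DesignError):
            mann_whitney([1.0], [2.0, 3.0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    shift=st.floats(0.1, 3.0),
    scale=st.floats(0.1, 2.0),
    seed=st.integers(0, 2**16),
)
def test_pooled_variance_location_invariant(shift, scale, seed):
    """Shifting all samples leaves variance unchanged; scaling scales it."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 1, size=(5, 12))
    s2, d = pooled_variance(make_matrix(values, n_case=6))
    s2_shift, _ = pooled_variance(make_matrix(values + shift, n_case=6))
    s2_scale, _ = pooled_variance(make_matrix(values * scale, n_case=6))
    assert d == 10
    np.testing.assert_allclose(s2_shift, s2, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(s2_scale, s2 * scale**2, rtol=1e-9)
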