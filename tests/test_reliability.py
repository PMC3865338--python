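"""Coefficient correctness: worked-example values, independent oracles,
Guttman inequalities and invariance properties."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_matrix, make_tensor, random_tensor

from psemetrics.data_model import (
    to_category_items,
    to_dichotomous_items,
    to_picture_items,
    worked_example,
)
from psemetrics.reliability import (
    InsufficientDataError,
    UndefinedCoefficientError,
    alpha,
    covariance_summary,
    fisher_mean_correlation,
    kr20,
    lambda1,
    lambda2,
    lambda4,
    lambda5,
    lambda6,
    lambda_suite,
    omega_total,
    reliability_report,
    report_for_matrix,
)

score_matrices = arrays(
    np.int64,
    st.tuples(st.integers(4, 15), st.integers(2, 6)),
    elements=st.integers(0, 4),
)


def _varying(scores):
    """True if every item and the total vary across subjects."""
    x = np.asarray(scores, dtype=float)
    return (x.var(axis=0) > 0).all() and x.sum(axis=1).var() > 0


class TestCovarianceSummary:
    def test_worked_example_category_correlations(self, demo):
        s = covariance_summary(to_category_items(demo))
        assert s.correlation[1, 2] == pytest.approx(1.0)
        assert s.correlation[0, 1] == pytest.approx(0.8367, abs=5e-4)

    def test_worked_example_picture_correlations(self, demo):
        s = covariance_summary(to_picture_items(demo))
        assert s.correlation[0, 1] == pytest.approx(-0.125)

    def test_variance_covariance_identity(self, rng):
        m = make_matrix(rng.integers(0, 4, (12, 5)))
        s = covariance_summary(m)
        assert s.total_variance == pytest.approx(
            s.variances.sum() + 2 * s.pairwise_covariance_sum()
        )

    def test_constant_item_flagged(self):
        m = make_matrix([[1, 0], [1, 1], [1, 0], [1, 1]])
        s = covariance_summary(m)
        assert s.zero_variance_items == ("i1",)
        assert np.isnan(s.correlation[0, 1])

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            covariance_summary(make_matrix([[1, 2]]))


class TestAlpha:
    def test_worked_example_both_modes(self, demo):
        assert alpha(to_category_items(demo)) == pytest.approx(21 / 22, abs=1e-12)
        assert alpha(to_picture_items(demo)) == pytest.approx(-0.4773, abs=5e-5)

    def test_two_identical_items(self):
        m = make_matrix(np.array([[1, 1], [2, 2], [3, 3], [1, 1]]))
        assert alpha(m) == pytest.approx(1.0)

    def test_zero_test_variance_rejected(self):
        m = make_matrix([[1, 0], [0, 1], [1, 0]])
        with pytest.raises(UndefinedCoefficientError):
            alpha(m)

    def test_denominator_convention_invariance(self, rng):
        m = make_matrix(rng.integers(0, 5, (10, 4)))
        assert alpha(m, ddof=0) == pytest.approx(alpha(m, ddof=1))
        assert lambda1(m, ddof=0) == pytest.approx(lambda1(m, ddof=1))
        assert lambda6(m, ddof=0) == pytest.approx(lambda6(m, ddof=1))


class TestLambdaSuite:
    def test_lambda1_alpha_identity_exact(self, demo):
        m = to_category_items(demo)
        n = m.n_items
        assert lambda1(m) == (n - 1) / n * alpha(m)
        assert lambda1(m) == pytest.approx(2 / 3 * (21 / 22))

    def test_two_identical_items_lambda2(self):
        m = make_matrix(np.array([[1, 1], [2, 2], [3, 3], [1, 1]]))
        assert lambda2(m) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(score_matrices)
    def test_guttman_inequality_and_identity(self, scores):
        if not _varying(scores):
            return
        m = make_matrix(scores)
        l1, l2, l5 = lambda_suite(m)
        a = alpha(m)
        assert l2 >= a - 1e-12
        assert l1 == pytest.approx((m.n_items - 1) / m.n_items * a)
        assert max(l1, l2, a, l5) <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(score_matrices, st.permutations(range(4)))
    def test_item_permutation_invariance(self, scores, perm4):
        if not _varying(scores):
            return
        m = make_matrix(scores)
        perm = list(np.argsort(np.random.default_rng(0).random(m.n_items)))
        mp = make_matrix(scores[:, perm])
        for fn in (lambda1, lambda2, alpha, lambda5, lambda6):
            assert fn(m) == pytest.approx(fn(mp))
        assert lambda4(m, "max").value == pytest.approx(lambda4(mp, "max").value)

    def test_subject_permutation_and_scale_invariance(self, rng):
        scores = rng.integers(0, 4, (12, 5))
        while not _varying(scores):
            scores = rng.integers(0, 4, (12, 5))
        m = make_matrix(scores)
        shuffled = make_matrix(scores[rng.permutation(12)])
        tripled = make_matrix(scores * 3)
        for fn in (lambda1, lambda2, alpha, lambda5, lambda6):
            assert fn(m) == pytest.approx(fn(shuffled))
            assert fn(m) == pytest.approx(fn(tripled))
        assert lambda4(m, "max").value == pytest.approx(
            lambda4(tripled, "max").value
        )


class TestLambda4:
    @staticmethod
    def brute_force_max(scores):
        """Independent enumeration of every balanced two-way split."""
        x = np.asarray(scores, dtype=float)
        n = x.shape[1]
        vt = x.sum(axis=1).var()
        best = -np.inf
        for k in range(n // 2, n // 2 + 1):
            for a in itertools.combinations(range(n), k):
                b = [j for j in range(n) if j not in a]
                va = x[:, list(a)].sum(axis=1).var()
                vb = x[:, b].sum(axis=1).var()
                best = max(best, 2 * (1 - (va + vb) / vt))
        return best

    def test_identical_items_any_strategy(self):
        m = make_matrix(np.array([[1, 1], [0, 0], [2, 2], [1, 1]]))
        for strategy in ("max", "first_last", "odd_even"):
            assert lambda4(m, strategy).value == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_halves(self, rng):
        # two independent halves with equal variance give lambda4 = 0
        a = rng.integers(0, 5, 4000)
        b = rng.permutation(a)
        m = make_matrix(np.column_stack([a, b]))
        assert lambda4(m, "max").value == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("n_items", [3, 4, 5, 6, 7, 8])
    def test_max_strategy_matches_brute_force(self, rng, n_items):
        scores = rng.integers(0, 4, (15, n_items))
        if not _varying(scores):
            pytest.skip("degenerate draw")
        m = make_matrix(scores)
        assert lambda4(m, "max").value == pytest.approx(
            self.brute_force_max(scores)
        )

    def test_worked_example_exhaustive(self, demo):
        m = to_category_items(demo)
        assert lambda4(m, "max").value == pytest.approx(
            self.brute_force_max(m.scores)
        )

    def test_split_labels_partition_items(self, rng):
        m = make_matrix(rng.integers(0, 4, (10, 6)))
        res = lambda4(m, "max")
        assert sorted(res.split[0] + res.split[1]) == sorted(m.items)

    def test_greedy_search_beats_fixed_splits(self, rng):
        scores = rng.integers(0, 3, (40, 24))  # above the exhaustive limit
        m = make_matrix(scores)
        vmax = lambda4(m, "max").value
        assert vmax >= lambda4(m, "first_last").value - 1e-9
        assert vmax >= lambda4(m, "odd_even").value - 1e-9


class TestLambda6:
    @staticmethod
    def regression_oracle(scores):
        """Item-on-rest least squares, population error variances."""
        x = np.asarray(scores, dtype=float)
        n_sub, n = x.shape
        vt = x.sum(axis=1).var()
        err = 0.0
        for j in range(n):
            rest = np.column_stack([np.ones(n_sub), np.delete(x, j, axis=1)])
            beta, *_ = np.linalg.lstsq(rest, x[:, j], rcond=None)
            resid = x[:, j] - rest @ beta
            err += resid.var()
        return 1 - err / vt

    def test_perfectly_correlated_pair_with_anchor(self):
        base = np.array([1, 2, 3, 4, 1, 3])
        scores = np.column_stack([base, base, base * 2])
        m = make_matrix(scores)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert lambda6(m) == pytest.approx(1.0, abs=1e-6)

    def test_uncorrelated_items_reduce_to_lambda1(self, rng):
        x = rng.integers(0, 5, (5000, 4))
        m = make_matrix(x)
        assert lambda6(m) == pytest.approx(lambda1(m), abs=0.02)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, (20, 5))
        if not _varying(scores):
            pytest.skip("degenerate draw")
        m = make_matrix(scores)
        assert lambda6(m) == pytest.approx(self.regression_oracle(scores))

    def test_zero_variance_item_excluded_with_warning(self, rng):
        scores = rng.integers(0, 4, (12, 4))
        scores[:, 2] = 1
        m = make_matrix(scores)
        with pytest.warns(UserWarning, match="zero-variance"):
            v = lambda6(m)
        assert np.isfinite(v)
        with pytest.raises(UndefinedCoefficientError):
            lambda6(m, strict=True)


class TestKR20:
    def test_matches_alpha_on_dichotomous(self, rng):
        t = random_tensor(rng, n=30, p=5, c=4)
        m = to_dichotomous_items(t)
        assert kr20(m) == pytest.approx(alpha(m))

    def test_independent_expression(self, rng):
        t = random_tensor(rng, n=25, p=4, c=3)
        m = to_dichotomous_items(t)
        x = m.scores.astype(float)
        p = x.mean(axis=0)
        n = x.shape[1]
        expected = n / (n - 1) * (1 - (p * (1 - p)).sum() / x.sum(axis=1).var())
        assert kr20(m) == pytest.approx(expected)

    def test_rejects_polytomous_matrix(self, demo):
        with pytest.raises(ValueError, match="dichotomous"):
            kr20(to_category_items(demo))


class TestOmegaTotal:
    def test_closed_form_one_factor_oracle(self):
        lam = np.full(6, 0.8)
        r = np.outer(lam, lam)
        np.fill_diagonal(r, 1.0)
        expected = 1 - (6 * (1 - 0.64)) / r.sum()
        res = omega_total(r)
        assert res.converged
        assert res.value == pytest.approx(expected, abs=1e-4)
        assert res.loadings[:, 0] == pytest.approx(lam, abs=1e-3)

    def test_unidimensional_limit_near_alpha(self):
        from psemetrics.synthetic import SimulationConfig, simulate_pse

        t = simulate_pse(
            SimulationConfig(n_subjects=1500, cue_sd=0.0, sawtooth=0.0, seed=5)
        )
        m = to_category_items(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert omega_total(m).value == pytest.approx(alpha(m), abs=0.03)

    def test_pure_noise_near_zero(self, rng):
        scores = rng.integers(0, 2, (3000, 6))
        m = make_matrix(scores)
        assert omega_total(m).value == pytest.approx(0.0, abs=0.08)

    def test_too_few_items_rejected(self):
        with pytest.raises(InsufficientDataError):
            omega_total(np.eye(2))


class TestFisherMean:
    def test_symmetric_pair(self):
        assert fisher_mean_correlation([0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_direct_tanh_mean(self, rng):
        rs = rng.uniform(-0.9, 0.9, 10)
        assert fisher_mean_correlation(rs) == pytest.approx(
            np.tanh(np.arctanh(rs).mean())
        )

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            fisher_mean_correlation([0.5, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_mean_correlation([])


class TestReliabilityReport:
    def test_layout_covers_scales_and_modes(self, rng):
        from psemetrics.data_model import FF_SCHEME, HS_SCHEME, attach_weighting

        hs = make_tensor(
            (rng.random((35, 6, 5)) < 0.3).astype(int),
            categories=HS_SCHEME.main_categories,
            pictures=tuple("ABCDEF"), scale_id="HS",
        )
        ff = make_tensor(
            (rng.random((35, 6, 6)) < 0.3).astype(int),
            categories=FF_SCHEME.main_categories,
            pictures=tuple("ABCDEF"), scale_id="FF",
        )
        hs_w, ff_w = attach_weighting(hs, ff)
        reports = reliability_report(hs_w, ff_w, include_weighting=True)
        assert reports[("HS", "category")].n_items == 6
        assert reports[("HS", "picture")].n_items == 6
        assert reports[("HS", "dichotomous")].n_items == 36
        assert reports[("FF", "category")].n_items == 7
        assert reports[("FF", "dichotomous")].n_items == 42
        assert reports[("FF", "dichotomous")].is_kr20
        no_w = reliability_report(hs_w, ff_w, include_weighting=False)
        assert no_w[("HS", "category")].n_items == 5
        assert no_w[("FF", "category")].n_items == 6

    def test_worked_example_report_values(self, demo):
        rep = report_for_matrix(to_category_items(demo), scale_id="demo")
        assert rep.alpha == pytest.approx(21 / 22, abs=1e-9)
        rep_p = report_for_matrix(to_picture_items(demo), scale_id="demo")
        assert rep_p.alpha == pytest.approx(-0.48, abs=0.005)

    def test_cell_errors_recorded_not_fatal(self):
        m = make_matrix([[1, 0], [0, 1], [1, 0], [0, 1]])  # zero total variance
        rep = report_for_matrix(m)
        assert "alpha" in rep.errors
        assert np.isnan(rep.alpha)
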