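"""Check-loss minimisation: solver correctness, oracle agreement, inference."""

import numpy as np
import pytest

from qrmeth import _fnsolver
from qrmeth.quantreg import (
    check_loss,
    fit_quantreg,
    infer_pvalues,
    oracle_fit,
)

TAUS = (0.5, 0.6, 0.75, 0.85, 0.95)


def quantile_by_grid_search(y, tau):
    """Independent 1-D oracle: the data point minimising the check loss."""
    losses = [check_loss(y - c, tau) for c in y]
    return y[int(np.argmin(losses))]


class TestCheckLoss:
    @pytest.mark.parametrize(
        "residuals,tau,expected",
        [
            ([0.0, 0.0, 0.0], 0.3, 0.0),
            ([1.0, -1.0], 0.5, 1.0),
            # 0.75*2 + 0.25*1 + 0.75*3
            ([2.0, -1.0, 3.0], 0.75, 4.0),
        ],
    )
    def test_values(self, residuals, tau, expected):
        assert check_loss(residuals, tau) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.2, 1.7])
    def test_tau_out_of_range(self, tau):
        with pytest.raises(ValueError, match="tau"):
            check_loss([1.0], tau)

    def test_zero_iff_zero_residuals(self, rng):
        u = rng.normal(size=20)
        assert check_loss(u, 0.7) > 0.0
        assert check_loss(np.zeros(20), 0.7) == 0.0


class TestFitQuantreg:
    def test_intercept_only_median(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_quantreg(np.ones((5, 1)), y, 0.5)
        assert fit.coefficients[0] == pytest.approx(3.0, abs=1e-9)

    def test_intercept_only_upper_quantile(self):
        # n*tau = 3.75 is non-integer, so the minimiser is the unique y_(4)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_quantreg(np.ones((5, 1)), y, 0.75)
        assert fit.coefficients[0] == pytest.approx(
            quantile_by_grid_search(y, 0.75), abs=1e-9
        )

    def test_objective_equals_loss_at_coefficients(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = rng.normal(size=15)
        fit = fit_quantreg(X, y, 0.85)
        assert fit.objective == pytest.approx(
            check_loss(y - X @ fit.coefficients, 0.85), abs=1e-8
        )
        assert fit.objective >= 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        k = int(rng.integers(1, 4))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))]) if k > 1 \
            else np.ones((n, 1))
        y = rng.normal(size=n)
        for tau in TAUS:
            fit = fit_quantreg(X, y, tau)
            assert fit.objective == pytest.approx(oracle_fit(X, y, tau), abs=1e-8)

    def test_residual_sign_counts_and_interpolation(self, rng):
        n, k = 60, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.normal(size=n)
        for tau in TAUS:
            r = fit_quantreg(X, y, tau).residuals
            assert np.sum(r < -1e-8) <= n * tau + 1e-9
            assert np.sum(r > 1e-8) <= n * (1.0 - tau) + 1e-9
            assert np.sum(np.abs(r) <= 1e-8) >= k

    def test_equivariance(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        base = fit_quantreg(X, y, 0.75)
        scaled = fit_quantreg(X, 3.0 * y, 0.75)
        assert scaled.objective == pytest.approx(3.0 * base.objective, rel=1e-7)
        assert np.allclose(scaled.coefficients, 3.0 * base.coefficients, atol=1e-7)
        delta = np.array([1.5, -0.5])
        shifted = fit_quantreg(X, y + X @ delta, 0.75)
        assert np.allclose(shifted.coefficients, base.coefficients + delta, atol=1e-7)

    def test_rank_deficient_design_names_columns(self, rng):
        X = np.ones((10, 2))  # duplicated column
        with pytest.raises(ValueError, match="rank deficient"):
            fit_quantreg(X, rng.normal(size=10), 0.5)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="more observations"):
            fit_quantreg(np.ones((2, 2)), np.zeros(2), 0.5)

    def test_cross_check_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(55)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
        for tau in (0.5, 0.85):
            ours = fit_quantreg(X, y, tau)
            theirs = sm.QuantReg(y, X).fit(q=tau)
            their_loss = check_loss(y - X @ theirs.params, tau)
            # same optimum: their (smoothed IRLS) solution cannot beat ours,
            # and must come close to the LP minimum
            assert their_loss >= ours.objective - 1e-6
            assert their_loss <= ours.objective * (1 + 1e-3)
        ours = fit_quantreg(X, y, 0.5)
        theirs = sm.QuantReg(y, X).fit(q=0.5)
        assert np.allclose(ours.coefficients, theirs.params, atol=1e-3)


class TestOracleFit:
    def test_non_negative_and_exact_fit(self, rng):
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        beta0 = np.array([0.5, -1.0])
        assert oracle_fit(X, X @ beta0, 0.7) == pytest.approx(0.0, abs=1e-12)
        assert oracle_fit(X, rng.normal(size=6), 0.7) >= 0.0

    def test_median_of_three(self):
        assert oracle_fit(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]), 0.5) == \
            pytest.approx(1.0, abs=1e-12)

    def test_rejects_large_instances(self, rng):
        with pytest.raises(ValueError, match="n <= 12"):
            oracle_fit(np.ones((20, 1)), rng.normal(size=20), 0.5)


class TestStructuredSolver:
    """The fast bootstrap engine must agree with the exact LP path."""

    @pytest.mark.parametrize("n_samples,n_probes", [(6, 2), (8, 4), (20, 10)])
    def test_objective_matches_lp(self, n_samples, n_probes, rng):
        from conftest import structured_design

        si, pi, y, X = structured_design(n_samples, n_probes, rng)
        for tau in TAUS:
            beta, ok, _ = _fnsolver.fit_structured(si, pi, y, n_samples, n_probes, tau)
            assert ok
            lp = fit_quantreg(X, y, tau)
            assert check_loss(y - X @ beta, tau) == pytest.approx(
                lp.objective, abs=1e-6
            )

    def test_single_probe_reduces_to_per_sample_quantiles(self, rng):
        # no probe block: each sample coefficient is its own tau-quantile
        N, reps = 5, 9
        si = np.repeat(np.arange(N), reps)
        pi = np.zeros(N * reps, dtype=np.int64)
        y = rng.normal(size=N * reps)
        beta, ok, _ = _fnsolver.fit_structured(si, pi, y, N, 1, 0.75)
        assert ok
        for s in range(N):
            ys = y[si == s]
            assert beta[s] == pytest.approx(quantile_by_grid_search(ys, 0.75), abs=1e-6)

    def test_bootstrap_reproducible_given_seed(self, rng):
        from conftest import structured_design

        si, pi, y, _ = structured_design(10, 5, rng)
        b1 = _fnsolver.bootstrap_sample_effects(
            si, pi, y, 10, 5, 0.85, 50, np.random.default_rng(42)
        )
        b2 = _fnsolver.bootstrap_sample_effects(
            si, pi, y, 10, 5, 0.85, 50, np.random.default_rng(42)
        )
        np.testing.assert_array_equal(b1, b2)


class TestInference:
    def test_zero_response_not_significant(self):
        X = np.ones((20, 1))
        inf = infer_pvalues(X, np.zeros(20), 0.75, seed=1)
        assert np.all(inf.p_values >= 0.5)

    def test_strong_effect_detected(self, rng):
        X = np.ones((30, 1))
        y = 2.0 + 0.1 * rng.normal(size=30)
        inf = infer_pvalues(X, y, 0.8, seed=2)
        assert inf.p_values[0] < 0.01

    def test_reproducible_given_seed(self, rng):
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = rng.normal(size=25)
        a = infer_pvalues(X, y, 0.6, seed=9)
        b = infer_pvalues(X, y, 0.6, seed=9)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            infer_pvalues(np.ones((20, 1)), np.arange(20.0), 0.5, n_boot=30, seed=3)

    def test_rank_method_reserved(self):
        with pytest.raises(NotImplementedError):
            infer_pvalues(np.ones((10, 1)), np.arange(10.0), 0.5, method="rank", seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            infer_pvalues(np.ones((10, 1)), np.arange(10.0), 0.5)

    def test_two_sided_alternative(self, rng):
        X = np.ones((30, 1))
        y = -2.0 + 0.1 * rng.normal(size=30)
        one = infer_pvalues(X, y, 0.5, seed=4, alternative="greater")
        two = infer_pvalues(X, y, 0.5, seed=4, alternative="two_sided")
        # strongly negative effect: not significant one-sided up, significant two-sided
        assert one.p_values[0] > 0.5
        assert two.p_values[0] < 0.01
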