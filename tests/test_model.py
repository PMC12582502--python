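"""Unit and property tests for the variational EM core."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from bmdd import (
    CountMatrix,
    FitConfig,
    Hyperparams,
    VariationalState,
    estep,
    fit,
    simulate_bmdd,
    surrogate_elbo,
)
from bmdd.impute import posterior_mean
from bmdd.model import (
    alpha_objective,
    h_value,
    update_alpha,
    update_beta,
    update_gamma,
    update_pi,
)
from bmdd.oracle import exact_mode_marginals, exact_posterior


class TestUpdateBeta:
    @pytest.mark.parametrize(
        "W, g, a0, a1, expected",
        [
            ([0.0], [0.0], [0.1], [5.0], [0.1]),
            ([7.0], [1.0], [0.1], [5.0], [12.0]),
            ([2.0, 3.0], [0.5, 0.5], [1.0, 1.0], [3.0, 3.0], [4.0, 5.0]),
        ],
    )
    def test_closed_form(self, W, g, a0, a1, expected):
        hp = Hyperparams(pi=np.full(len(W), 0.5), alpha0=a0, alpha1=a1)
        np.testing.assert_allclose(update_beta(np.array(W), np.array(g), hp), expected)

    def test_dimension_mismatch_rejected(self):
        hp = Hyperparams(pi=[0.5], alpha0=[1.0], alpha1=[2.0])
        with pytest.raises(ValueError):
            update_beta(np.array([1.0, 2.0]), np.array([0.5]), hp)

    def test_non_finite_rejected(self):
        hp = Hyperparams(pi=[0.5], alpha0=[1.0], alpha1=[2.0])
        with pytest.raises(ValueError):
            update_beta(np.array([np.nan]), np.array([0.5]), hp)


class TestHValue:
    def test_single_taxon_unit_alpha_is_zero(self):
        hp = Hyperparams(pi=[0.5], alpha0=[1.0], alpha1=[1.0])
        assert h_value(0, 0, np.array([2.0]), np.array([0.3]), hp) == pytest.approx(0.0)

    def test_symmetric_modes_give_equal_h(self):
        hp = Hyperparams(pi=[0.4, 0.4, 0.4], alpha0=[1.5, 2.0, 0.7], alpha1=[1.5, 2.0, 0.7])
        beta = np.array([3.0, 1.0, 2.5])
        gamma = np.array([0.2, 0.9, 0.5])
        for j in range(3):
            assert h_value(j, 0, beta, gamma, hp) == pytest.approx(
                h_value(j, 1, beta, gamma, hp)
            )

    def test_matches_high_precision_recomputation(self, small_hp):
        """Term-by-term recomputation with 40-digit symbolic log-gamma/digamma."""
        beta = np.array([4.2, 0.7, 9.1])
        gamma = np.array([0.3, 0.8, 0.1])
        for j in range(3):
            for d in (0, 1):
                a_jd = (small_hp.alpha1 if d else small_hp.alpha0)[j]
                mix = gamma * small_hp.alpha1 + (1 - gamma) * small_hp.alpha0
                rest = mix.sum() - mix[j]
                expected = (
                    sympy.loggamma(sympy.Float(a_jd + rest, 40))
                    + (a_jd - 1)
                    * (
                        sympy.digamma(sympy.Float(beta[j], 40))
                        - sympy.digamma(sympy.Float(beta.sum(), 40))
                    )
                    - sympy.loggamma(sympy.Float(a_jd, 40))
                )
                got = h_value(j, d, beta, gamma, small_hp)
                assert got == pytest.approx(float(expected.evalf(40)), rel=1e-10)


class TestUpdateGamma:
    def test_zero_prior_forces_zero(self):
        hp = Hyperparams(pi=[0.0, 0.5], alpha0=[0.1, 0.1], alpha1=[2.0, 2.0])
        assert update_gamma(0, np.array([1.0, 1.0]), np.array([0.5, 0.5]), hp) == 0.0

    def test_symmetric_evidence_gives_half(self):
        hp = Hyperparams(pi=[0.5, 0.5], alpha0=[2.0, 2.0], alpha1=[2.0, 2.0])
        g = update_gamma(0, np.array([3.0, 4.0]), np.array([0.5, 0.5]), hp)
        assert g == pytest.approx(0.5)

    def test_fixed_point_matches_enumeration(self, small_hp):
        """gamma at the mean-field fixed point tracks exact P(delta=1 | W)."""
        W, _ = simulate_bmdd(small_hp, 20, 2000, seed=3)
        state = estep(W, small_hp)
        exact = np.stack(
            [exact_mode_marginals(W.counts[i], small_hp) for i in range(20)]
        )
        assert np.abs(state.gamma - exact).mean() <= 0.05


class TestUpdatePi:
    def test_column_means(self):
        g = np.array([[0.0, 1.0], [1.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(update_pi(g), [0.5, 0.5])

    def test_all_zero_gamma(self):
        np.testing.assert_allclose(update_pi(np.zeros((3, 2))), [0.0, 0.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_independent_summation(self, seed):
        g = np.random.default_rng(seed).uniform(size=(7, 4))
        expected = np.array([sum(g[i, j] for i in range(7)) / 7 for j in range(4)])
        np.testing.assert_allclose(update_pi(g), expected, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            update_pi(np.empty((0, 3)))


class TestAlphaObjective:
    def test_all_unit_terms_vanish(self):
        val = alpha_objective(
            np.array([1.0]), np.array([2.0]), np.zeros((1, 1)), np.ones((1, 1))
        )
        assert val == pytest.approx(0.0)

    def test_label_switching_symmetry(self):
        rng = np.random.default_rng(5)
        a0, a1 = rng.uniform(0.1, 3, 4), rng.uniform(0.1, 3, 4)
        gamma = rng.uniform(size=(6, 4))
        beta = rng.uniform(0.5, 5, size=(6, 4))
        assert alpha_objective(a0, a1, gamma, beta) == pytest.approx(
            alpha_objective(a1, a0, 1 - gamma, beta)
        )

    def test_matches_high_precision_recomputation(self):
        rng = np.random.default_rng(6)
        a0, a1 = rng.uniform(0.1, 2, 2), rng.uniform(1, 5, 2)
        gamma = rng.uniform(size=(3, 2))
        beta = rng.uniform(0.5, 5, size=(3, 2))
        abar = gamma * a1 + (1 - gamma) * a0
        expected = sympy.Float(0, 40)
        for i in range(3):
            expected += sympy.loggamma(sympy.Float(abar[i].sum(), 40))
            for j in range(2):
                expected += (abar[i, j] - 1) * (
                    sympy.digamma(sympy.Float(beta[i, j], 40))
                    - sympy.digamma(sympy.Float(beta[i].sum(), 40))
                )
                expected -= gamma[i, j] * sympy.loggamma(sympy.Float(a1[j], 40))
                expected -= (1 - gamma[i, j]) * sympy.loggamma(sympy.Float(a0[j], 40))
        assert alpha_objective(a0, a1, gamma, beta) == pytest.approx(
            float(expected.evalf(40)), rel=1e-10
        )

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            alpha_objective(np.array([-1.0]), np.array([1.0]), np.zeros((1, 1)), np.ones((1, 1)))


class TestUpdateAlpha:
    def test_recovers_common_concentration_vs_grid(self):
        """With equal modes and gamma=0.5 the optimum matches a scalar grid search."""
        c = 3.0
        hp = Hyperparams(pi=np.full(4, 0.5), alpha0=np.full(4, c), alpha1=np.full(4, c))
        W, _ = simulate_bmdd(hp, 150, 5000, seed=3)
        gamma = np.full((150, 4), 0.5)
        beta = W.counts + c
        warm = Hyperparams(pi=np.full(4, 0.5), alpha0=np.full(4, 1.0), alpha1=np.full(4, 1.0))
        a0, a1 = update_alpha(gamma, beta, warm, FitConfig())
        grid = np.linspace(0.5, 10, 200)
        vals = [alpha_objective(np.full(4, g), np.full(4, g), gamma, beta) for g in grid]
        best = grid[int(np.argmax(vals))]
        # with symmetric responsibilities both modes collapse to one scalar
        assert np.allclose(a0, a1, rtol=1e-3)
        assert np.abs(a0.mean() - best) < 0.2
        assert np.abs(a0.mean() - c) < 1.0

    def test_never_worse_than_warm_start(self):
        rng = np.random.default_rng(9)
        gamma = rng.uniform(size=(10, 3))
        beta = rng.uniform(0.5, 8, size=(10, 3))
        warm = Hyperparams(pi=np.full(3, 0.5), alpha0=rng.uniform(0.1, 1, 3), alpha1=rng.uniform(1, 5, 3))
        a0, a1 = update_alpha(gamma, beta, warm, FitConfig())
        f_warm = alpha_objective(warm.alpha0, warm.alpha1, gamma, beta)
        assert alpha_objective(a0, a1, gamma, beta) >= f_warm - 1e-9


class TestSurrogateElbo:
    def test_single_taxon_closed_form(self):
        """m=1: the simplex is degenerate and only mixture/entropy terms remain."""
        from scipy.special import gammaln

        W = CountMatrix(np.array([[5]]))
        hp = Hyperparams(pi=[0.4], alpha0=[0.5], alpha1=[3.0])
        g = 0.3
        beta = np.array([[5.0 + g * 3.0 + (1 - g) * 0.5]])
        state = VariationalState(beta=beta, gamma=np.array([[g]]))
        abar = g * 3.0 + (1 - g) * 0.5
        expected = (
            gammaln(abar)
            - g * gammaln(3.0)
            - (1 - g) * gammaln(0.5)
            + g * np.log(0.4)
            + (1 - g) * np.log(0.6)
            - g * np.log(g)
            - (1 - g) * np.log(1 - g)
        )
        assert surrogate_elbo(W, state, hp) == pytest.approx(float(expected))

    def test_bounded_by_exact_log_marginal(self, small_hp):
        W, _ = simulate_bmdd(small_hp, 8, 800, seed=13)
        state = estep(W, small_hp)
        elbo = surrogate_elbo(W, state, small_hp)
        exact = sum(exact_posterior(W.counts[i], small_hp).log_marginal for i in range(8))
        assert elbo <= exact + 1e-9

    def test_trace_non_decreasing(self):
        hp = Hyperparams(
            pi=np.linspace(0.2, 0.8, 6),
            alpha0=np.full(6, 0.05),
            alpha1=np.linspace(1, 8, 6),
        )
        W, _ = simulate_bmdd(hp, 40, 3000, seed=17)
        _, state = fit(W, FitConfig(seed=0, max_iter=60))
        steps = np.diff(state.objective_trace)
        assert steps.size > 0 and (steps >= -1e-6).all()


class TestFit:
    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            fit(CountMatrix(np.array([[3], [4]])))

    def test_no_uncertainty_limit(self):
        """Identical zero-free rows at huge depth pin the posterior to the data."""
        row = (np.array([0.2, 0.3, 0.5]) * 1_000_000).astype(int)
        W = CountMatrix(np.tile(row, (15, 1)))
        _, state = fit(W, FitConfig(seed=0, max_iter=50))
        X = posterior_mean(state).values
        assert np.abs(X - row / row.sum()).max() < 1e-3

    def test_dirichlet_multinomial_limit_any_gamma(self):
        """Equal modes collapse the posterior mean to (W + a) / (N + sum a)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = rng.integers(2, 5)
            a = rng.uniform(0.2, 4, m)
            hp = Hyperparams(pi=rng.uniform(0, 0.9, m), alpha0=a, alpha1=a)
            W = CountMatrix(rng.integers(0, 50, size=(4, m)) + rng.integers(0, 2, size=(4, m)))
            state = estep(W, hp, gamma0=rng.uniform(size=(4, m)), max_sweeps=3)
            expected = (W.counts + a) / (W.totals[:, None] + a.sum())
            np.testing.assert_allclose(posterior_mean(state).values, expected, atol=1e-6)

    def test_depth_consistency(self, small_hp):
        comp = np.array([0.6, 0.1, 0.3])
        W = CountMatrix((comp * 1_000_000).astype(int)[None, :])
        state = estep(W, small_hp)
        np.testing.assert_allclose(posterior_mean(state).values[0], comp, atol=1e-3)

    def test_mode_label_invariance(self, small_counts):
        hp = Hyperparams(pi=[0.3, 0.6, 0.2], alpha0=[0.1, 0.2, 0.3], alpha1=[2.0, 3.0, 4.0])
        swapped = Hyperparams(pi=1 - hp.pi, alpha0=hp.alpha1, alpha1=hp.alpha0)
        rng = np.random.default_rng(2)
        gamma = rng.uniform(size=small_counts.shape)
        beta = small_counts.counts + gamma * hp.alpha1 + (1 - gamma) * hp.alpha0
        s1 = VariationalState(beta=beta, gamma=gamma)
        s2 = VariationalState(beta=beta, gamma=1 - gamma)
        assert surrogate_elbo(small_counts, s1, hp) == pytest.approx(
            surrogate_elbo(small_counts, s2, swapped)
        )
        np.testing.assert_allclose(posterior_mean(s1).values, posterior_mean(s2).values)

    def test_canonical_ordering_and_determinism(self, small_counts):
        hp1, st1 = fit(small_counts, FitConfig(seed=7, max_iter=30))
        hp2, st2 = fit(small_counts, FitConfig(seed=7, max_iter=30))
        assert (hp1.alpha0 <= hp1.alpha1).all()
        np.testing.assert_array_equal(st1.beta, st2.beta)
        np.testing.assert_array_equal(hp1.pi, hp2.pi)

    def test_all_zero_taxon_handled_with_warning(self, caplog):
        rng = np.random.default_rng(31)
        W = rng.integers(1, 30, size=(10, 3))
        W[:, 1] = 0
        with caplog.at_level("WARNING"):
            hp, state = fit(CountMatrix(W), FitConfig(seed=0, max_iter=10))
        assert "all-zero" in caplog.text
        assert np.isfinite(state.beta).all()
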