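from fractions import Fraction

import numpy as np
import pytest

from conftest import make_methylome
from methylhmm.genome_context import CONTEXTS_6
from methylhmm.hmm_core import (
    HMMParams,
    baum_welch,
    conversion_rates,
    default_params,
    emission_prob,
    forward_backward,
    recalibrated_levels,
    transition_matrix,
    update_emissions,
    update_transitions,
)
from methylhmm.simulate import default_truth_params, simulate_methylome
from oracles import eq5_transition_update, eq6_emission_update, exact_binomial_pmf


def random_params(rng, C=6, D_range=(1.0, 100.0)):
    TC = C * C
    p = np.sort(rng.uniform(0.01, 0.99, size=(2, C)), axis=0)
    A0 = rng.dirichlet([1.0, 1.0], size=(TC, 2))
    D = rng.uniform(*D_range, size=TC)
    pi = rng.dirichlet([1.0, 1.0])
    return HMMParams(p=p, A0=A0, D=D, pi=pi, contexts=CONTEXTS_6)


def random_methylome(rng, T, lam=3.0):
    positions = np.cumsum(rng.integers(1, 40, size=T))
    ctx = rng.integers(0, 6, size=T)
    r = rng.poisson(lam, size=T)
    m = rng.binomial(r, rng.uniform(0, 1, size=T))
    return make_methylome(positions, m, r, contexts=ctx)


class TestEmissionProb:
    def test_zero_coverage_emits_one(self):
        assert emission_prob(0, 0, 0.3) == 1.0
        assert emission_prob(0, 0, 0.0) == 1.0

    def test_certain_success(self):
        assert emission_prob(3, 3, 1.0) == pytest.approx(1.0)

    def test_matches_exact_rational_evaluation(self):
        expected = float(exact_binomial_pmf(2, 10, Fraction(1, 10)))
        assert emission_prob(2, 10, 0.1) == pytest.approx(expected, abs=1e-15)

    def test_m_greater_than_r_rejected(self):
        with pytest.raises(ValueError):
            emission_prob(5, 3, 0.5)


class TestTransitionMatrix:
    def test_zero_distance_returns_a0(self):
        A0 = np.array([[0.8, 0.2], [0.3, 0.7]])
        assert np.array_equal(transition_matrix(A0, 0.0, 30.0), A0)

    def test_infinite_distance_is_uniform(self):
        A0 = np.array([[0.99, 0.01], [0.01, 0.99]])
        A = transition_matrix(A0, 1e9 * 30.0, 30.0)
        assert np.allclose(A, 0.5, atol=1e-6)

    def test_one_decay_length(self):
        A0 = np.array([[0.8, 0.2], [0.3, 0.7]])
        A = transition_matrix(A0, 30.0, 30.0)
        e = np.exp(-1.0)
        assert A[0, 0] == pytest.approx(0.8 * e + 0.5 * (1 - e), abs=1e-15)

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.eye(2), 1.0, 0.0)


class TestForwardBackward:
    def test_single_methylated_read_forces_m(self):
        meth = make_methylome([10], [1], [1])
        params = default_params(CONTEXTS_6)
        params.p[:, :] = [[0.0], [1.0]] * np.ones((2, 6))
        gamma, xi, ll = forward_backward(meth, params)
        assert np.allclose(gamma[0], [0.0, 1.0])

    def test_all_missing_data_gives_uniform_posteriors(self):
        meth = make_methylome([1, 5, 30, 31], [0] * 4, [0] * 4)
        params = default_params(CONTEXTS_6)  # symmetric A0, uniform pi
        gamma, xi, ll = forward_backward(meth, params)
        assert np.allclose(gamma, 0.5, atol=1e-12)
        assert ll == pytest.approx(0.0, abs=1e-12)  # all emissions are 1

    def test_matches_exhaustive_enumeration(self, rng):
        from oracles import enumerate_paths

        for _ in range(10):
            T = int(rng.integers(2, 8))
            meth = random_methylome(rng, T)
            params = random_params(rng)
            gamma, xi, ll = forward_backward(meth, params)
            B = np.empty((T, 2))
            for i in range(2):
                B[:, i] = [
                    float(emission_prob(m, r, params.p[i, c]))
                    for m, r, c in zip(meth.m, meth.r, meth.context)
                ]
            B[meth.r == 0] = 1.0
            d = np.diff(meth.position)
            tc = meth.context[:-1] * 6 + meth.context[1:]
            A = np.stack(
                [
                    transition_matrix(params.A0[tc[t]], d[t], params.D[tc[t]])
                    for t in range(T - 1)
                ]
            )
            ll_o, gamma_o, xi_o = enumerate_paths(B, A, params.pi)
            assert ll == pytest.approx(ll_o, abs=1e-9)
            assert np.allclose(gamma, gamma_o, atol=1e-9)
            assert np.allclose(xi, xi_o, atol=1e-9)

    def test_posterior_rows_sum_to_one(self, rng):
        meth = random_methylome(rng, 200)
        gamma, xi, ll = forward_backward(meth, random_params(rng))
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_chromosomes_are_independent_chains(self, rng):
        half = random_methylome(rng, 5)
        both = make_methylome(
            np.concatenate([half.position, half.position]),
            np.concatenate([half.m, half.m]),
            np.concatenate([half.r, half.r]),
            contexts=np.concatenate([half.context, half.context]),
            chrom=["chr1"] * 5 + ["chr2"] * 5,
        )
        params = random_params(rng)
        _, _, ll_half = forward_backward(half, params)
        _, _, ll_both = forward_backward(both, params)
        assert ll_both == pytest.approx(2 * ll_half, abs=1e-9)

    def test_all_invalid_context_rejected(self):
        meth = make_methylome([1, 2], [0, 0], [0, 0], contexts=[-1, -1])
        with pytest.raises(ValueError, match="no sites"):
            forward_backward(meth, default_params(CONTEXTS_6))


class TestUpdates:
    def test_zero_distance_reduces_to_classical_update(self, rng):
        # all sites at the same spot is impossible; emulate d=0 via huge D
        # instead: with D -> inf, e^{-d/D} ~ 1 and A ~ A0, so the update
        # must approach sum_t xi_ijt / sum_tj xi_ijt per transition context.
        T = 30
        meth = random_methylome(rng, T)
        params = random_params(rng, D_range=(1e12, 2e12))
        gamma, xi, _ = forward_backward(meth, params)
        new = update_transitions(xi, meth, params)
        tc = meth.context[:-1] * 6 + meth.context[1:]
        for c in np.unique(tc):
            sel = tc == c
            classical = xi[sel].sum(axis=0)
            classical = classical / classical.sum(axis=1, keepdims=True)
            assert np.allclose(new[c], classical, atol=1e-6)

    def test_transition_update_matches_equation_oracle(self, rng):
        meth = random_methylome(rng, 6)
        params = random_params(rng)
        gamma, xi, _ = forward_backward(meth, params)
        new = update_transitions(xi, meth, params)
        d = np.diff(meth.position)
        tc = meth.context[:-1] * 6 + meth.context[1:]
        expected = eq5_transition_update(xi, d, tc, params.A0, params.D, 6)
        assert np.allclose(new, expected, atol=1e-12)
        assert np.allclose(new.sum(axis=2), 1.0, atol=1e-12)

    def test_emission_update_pools_weighted_counts(self):
        meth = make_methylome([1, 5], [1, 3], [2, 4], contexts=[0, 0])
        gamma = np.array([[0.0, 1.0], [0.0, 1.0]])
        p = update_emissions(gamma, meth, prev_p=np.full((2, 6), 0.5))
        assert p[1, 0] == pytest.approx(4 / 6)
        assert p[0, 0] == pytest.approx(0.5)  # kept: zero U-weight

    def test_emission_update_matches_equation_oracle(self, rng):
        meth = random_methylome(rng, 40)
        gamma = rng.dirichlet([1, 1], size=40)
        prev = np.full((2, 6), 0.5)
        p = update_emissions(gamma, meth, prev_p=prev)
        expected = eq6_emission_update(gamma, meth.m, meth.r, meth.context, 6, prev)
        assert np.allclose(p, expected, atol=1e-14)

    def test_zero_coverage_sites_contribute_nothing(self, rng):
        meth = random_methylome(rng, 40)
        covered = meth.subset(meth.r > 0)
        gamma = rng.dirichlet([1, 1], size=40)
        p_all = update_emissions(gamma, meth)
        p_cov = update_emissions(gamma[meth.r > 0], covered)
        np.testing.assert_allclose(
            np.nan_to_num(p_all), np.nan_to_num(p_cov), atol=1e-14
        )


class TestBaumWelch:
    def test_converged_parameters_are_a_fixed_point(self):
        meth, _ = simulate_methylome(3000, seed=4)
        fit = baum_welch(
            meth, init=default_params(CONTEXTS_6, D=30.0), tol=1e-10, max_iter=400
        )
        refit = baum_welch(meth, init=fit.params, tol=1e-4, max_iter=5)
        assert len(refit.loglik_trace) <= 2
        assert np.allclose(refit.params.p, fit.params.p, atol=1e-5)

    def test_label_convention_enforced(self):
        meth, _ = simulate_methylome(3000, seed=4)
        flipped = default_params(CONTEXTS_6, D=30.0)
        flipped.p[:] = flipped.p[::-1]  # start with M below U
        fit = baum_welch(meth, init=flipped, max_iter=150)
        assert np.all(fit.params.p[0] <= fit.params.p[1])
        assert fit.conversion_rate_u > 0.9

    def test_tie_breaks_to_unmethylated(self):
        meth = make_methylome([1, 10], [0, 0], [0, 0])
        params = default_params(CONTEXTS_6)
        fit = baum_welch(meth, init=params, max_iter=1)
        assert np.all(fit.status == "U")

    def test_undefined_context_sites_excluded_but_reported(self):
        meth = make_methylome([1, 5, 9], [0, 2, 0], [0, 4, 0], contexts=[0, 0, -1])
        fit = baum_welch(meth, init=default_params(CONTEXTS_6, D=30.0), max_iter=20)
        assert fit.status[2] == "undefined"
        assert np.isnan(fit.gamma[2]).all()
        assert np.isfinite(fit.gamma[:2]).all()


class TestDerivedQuantities:
    def test_recalibrated_levels_formula(self):
        params = default_params(CONTEXTS_6)
        params.p[:, 0] = [0.01, 0.81]
        gam = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        rc = recalibrated_levels(gam, params, np.array([0, 0, 0]))
        assert rc[0] == pytest.approx(0.01)
        assert rc[1] == pytest.approx(0.81)
        assert rc[2] == pytest.approx(0.01 * 0.5 + 0.81 * 0.5)

    def test_conversion_rate_mapping(self):
        params = default_params(CONTEXTS_6)
        params.p[0, 0] = 0.011
        params.p[1, 0] = 0.84
        cu, cm = conversion_rates(params)
        assert cu == pytest.approx(0.989)
        assert cm == pytest.approx(0.16)
        params.p[0, 0] = 0.0
        assert conversion_rates(params)[0] == 1.0

    def test_conversion_rate_recovered_from_simulation(self):
        truth = default_truth_params(p_u=0.01)
        meth, _ = simulate_methylome(60_000, params=truth, seed=12)
        fit = baum_welch(meth, init=default_params(CONTEXTS_6, D=30.0), max_iter=200)
        assert fit.conversion_rate_u == pytest.approx(0.99, abs=0.003)
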