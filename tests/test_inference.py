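import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fepnet import (
    Belief,
    Observation,
    compute_free_energy,
    normalize_likelihood,
    prediction_error,
    sample_action,
    update_belief,
)
from fepnet.exceptions import ContractError, DomainError
from fepnet.generative_model import FIRING_PREDICTED
from fepnet.inference import FreeEnergyTrace, log_messages
from conftest import _random_likelihoods as random_likelihoods


def _softmax(v):
    e = np.exp(v - np.max(v))
    return e / e.sum()


UNIFORM = Belief(np.zeros(2))
B_UNIF = np.full((2, 2), 0.5)


class TestPredictionError:
    def test_zero_at_fixed_point(self, rng):
        liks = random_likelihoods(rng, 3)
        obs = [1, 0, 1]
        m = log_messages(obs, liks, B_UNIF, UNIFORM)
        belief = Belief(m.copy())
        eps = prediction_error(belief, obs, liks, B_UNIF, UNIFORM)
        assert np.allclose(eps, 0.0, atol=1e-12)

    def test_zero_precision_synapses_contribute_nothing(self):
        liks = [(np.full((2, 2), 0.5), 0.0)] * 4
        eps = prediction_error(UNIFORM, [1, 1, 0, 1], liks,
                               FIRING_PREDICTED, UNIFORM)
        only_b = prediction_error(UNIFORM, [], [], FIRING_PREDICTED, UNIFORM)
        assert np.allclose(eps, only_b)

    def test_two_synapse_example_matches_scalar_arithmetic(self):
        # independent scalar oracle: evaluate each term of the error with
        # plain math.log and centre it, then compare
        abar = np.array([[0.75, 0.25], [0.25, 0.75]])
        liks = [(abar, 0.5), (abar, 0.5)]
        floor = 1e-16
        msg = [
            2 * 0.5 * math.log(abar[1, h])                 # two obs = 1
            + math.log(max(FIRING_PREDICTED[h, :] @ [0.5, 0.5], floor))
            for h in (0, 1)
        ]
        raw = [math.log(0.5) - msg[h] for h in (0, 1)]
        centred = np.array(raw) - np.mean(raw)
        eps = prediction_error(UNIFORM, [1, 1], liks, FIRING_PREDICTED,
                               UNIFORM)
        assert np.allclose(eps, centred, atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        liks = random_likelihoods(rng, 2)
        with pytest.raises(ContractError):
            prediction_error(UNIFORM, [1], liks, B_UNIF, UNIFORM)


class TestUpdateBelief:
    def test_fixed_point_is_unchanged(self, rng):
        liks = random_likelihoods(rng, 2)
        obs = [0, 1]
        m = log_messages(obs, liks, B_UNIF, UNIFORM)
        belief = Belief(m.copy())
        out = update_belief(belief, obs, liks, B_UNIF, UNIFORM)
        assert np.allclose(out.probs, belief.probs, atol=1e-9)

    def test_converges_to_softmax_of_messages(self, rng):
        for _ in range(20):
            liks = random_likelihoods(rng, 4)
            obs = rng.integers(0, 2, size=4)
            m = log_messages(obs, liks, B_UNIF, UNIFORM)
            out = update_belief(UNIFORM, obs, liks, B_UNIF, UNIFORM,
                                n_iter=400, tol=1e-9)
            assert np.allclose(out.probs, _softmax(m), atol=1e-6)

    def test_messages_favouring_firing_increase_expectation(self):
        liks = [(np.array([[0.75, 0.25], [0.25, 0.75]]), 0.5)] * 3
        belief = UNIFORM
        last = belief.firing_expectation
        for _ in range(5):
            belief = update_belief(belief, [1, 1, 1], liks, B_UNIF, UNIFORM,
                                   n_iter=1)
            assert belief.firing_expectation > last
            last = belief.firing_expectation

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_probs_stay_on_simplex_along_random_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        liks = random_likelihoods(rng, 3)
        belief = Belief(rng.normal(0, 3, size=2))
        prev = Belief(rng.normal(0, 3, size=2))
        for _ in range(10):
            obs = rng.integers(0, 2, size=3)
            belief = update_belief(belief, obs, liks, B_UNIF, prev, n_iter=4)
            p = belief.probs
            assert np.all(p >= 0) and abs(p.sum() - 1.0) < 1e-12

    def test_free_energy_non_increasing_with_fixed_messages(self, rng):
        for _ in range(20):
            liks = random_likelihoods(rng, 3)
            obs = rng.integers(0, 2, size=3)
            belief = Belief(rng.normal(0, 4, size=2))
            prev = Belief(rng.normal(0, 2, size=2))
            f_prev = compute_free_energy(belief, obs, liks, B_UNIF, prev)
            for _ in range(30):
                belief = update_belief(belief, obs, liks, B_UNIF, prev,
                                       n_iter=1)
                f = compute_free_energy(belief, obs, liks, B_UNIF, prev)
                assert f <= f_prev + 1e-10
                f_prev = f


class TestFreeEnergy:
    def test_all_uniform_single_synapse_gives_ln2(self):
        liks = [(np.full((2, 2), 0.5), 1.0)]
        f = compute_free_energy(UNIFORM, [1], liks, B_UNIF, UNIFORM)
        assert f == pytest.approx(math.log(2.0), abs=1e-12)

    def test_bound_tight_at_exact_posterior(self, rng):
        # one-step model at unit precision: the likelihood is a proper
        # probability table, so F at the exact posterior equals -ln P(o)
        base = rng.uniform(0.1, 1.0, size=(2, 2))
        abar = normalize_likelihood(base, 1.0)
        prior = np.array([0.3, 0.7])
        b_prev = np.column_stack([prior, prior])
        o = 1
        joint = abar[o, :] * prior
        posterior = Belief.from_probs(joint / joint.sum())
        f = compute_free_energy(posterior, [o], [(abar, 1.0)], b_prev,
                                UNIFORM)
        assert f == pytest.approx(-math.log(joint.sum()), abs=1e-9)

    def test_any_other_belief_gives_strictly_larger_f(self, rng):
        base = rng.uniform(0.1, 1.0, size=(2, 2))
        abar = normalize_likelihood(base, 1.0)
        prior = np.array([0.3, 0.7])
        b_prev = np.column_stack([prior, prior])
        joint = abar[1, :] * prior
        posterior = joint / joint.sum()
        f_star = compute_free_energy(Belief.from_probs(posterior), [1],
                                     [(abar, 1.0)], b_prev, UNIFORM)
        for delta in (0.05, -0.1, 0.2):
            p = np.clip(posterior + [delta, -delta], 1e-6, 1 - 1e-6)
            p = p / p.sum()
            f = compute_free_energy(Belief.from_probs(p), [1],
                                    [(abar, 1.0)], b_prev, UNIFORM)
            assert f > f_star

    def test_gradient_matches_finite_difference_through_softmax_jacobian(
        self, rng
    ):
        # dF/d(upsilon) = s * (eps - s.eps): check the analytic error
        # against a central finite difference of F in potential space
        for _ in range(25):
            liks = random_likelihoods(rng, 3)
            obs = rng.integers(0, 2, size=3)
            prev = Belief(rng.normal(0, 2, size=2))
            ups = rng.normal(0, 2, size=2)
            belief = Belief(ups)
            eps = prediction_error(belief, obs, liks, B_UNIF, prev)
            s = belief.probs
            grad_analytic = s * (eps - s @ eps)
            h = 1e-6
            grad_fd = np.empty(2)
            for a in range(2):
                up = ups.copy()
                up[a] += h
                fp = compute_free_energy(Belief(up), obs, liks, B_UNIF, prev)
                up[a] -= 2 * h
                fm = compute_free_energy(Belief(up), obs, liks, B_UNIF, prev)
                grad_fd[a] = (fp - fm) / (2 * h)
            denom = max(np.abs(grad_fd).max(), 1e-3)
            assert np.abs(grad_analytic - grad_fd).max() / denom < 1e-4


class TestSampleAction:
    def test_degenerate_expectations(self, rng):
        assert all(sample_action(1.0, rng) == 1 for _ in range(100))
        assert all(sample_action(0.0, rng) == 0 for _ in range(100))

    def test_fair_expectation_matches_binomial_oracle(self):
        rng = np.random.default_rng(7)
        draws = np.array([sample_action(0.5, rng) for _ in range(10_000)])
        se = 0.5 / math.sqrt(10_000)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_out_of_range_raises(self, rng):
        with pytest.raises(DomainError):
            sample_action(1.5, rng)


class TestObservationAndTrace:
    def test_observation_entries_validated(self):
        with pytest.raises(ContractError):
            Observation(np.array([0, 2]))

    def test_sliding_mean_of_constant_is_constant(self):
        tr = FreeEnergyTrace(np.full((50, 4), 3.25))
        assert np.allclose(tr.sliding_mean(15), 3.25)
        assert np.allclose(tr.ensemble_mean(), 3.25)
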