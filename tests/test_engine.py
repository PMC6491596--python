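import numpy as np
import pytest

import fepnet
from fepnet import (
    Belief,
    OscillatorWindow,
    SimulationConfig,
    StimulusProtocol,
    build_transition,
    compute_free_energy,
    fired_from_belief,
    normalize_likelihood,
    update_belief,
)
from fepnet.engine import Network, apply_stimulus, run_experiment
from fepnet.exceptions import ConfigError


class TestDeterminism:
    def test_identical_config_gives_bit_identical_results(self):
        cfg = fepnet.synchrony_config(seed=3, n_steps=120)
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        assert np.array_equal(a.raster, b.raster)
        assert np.array_equal(a.fired, b.fired)
        assert np.array_equal(a.firing_prob, b.firing_prob)
        assert np.array_equal(a.free_energy, b.free_energy)

    def test_action_seed_changes_spikes_but_not_architecture(self):
        a = run_experiment(fepnet.synchrony_config(seed=3, n_steps=80))
        b = run_experiment(
            fepnet.synchrony_config(seed=3, n_steps=80).replace(action_seed=99)
        )
        assert np.array_equal(a.windows, b.windows)
        assert not np.array_equal(a.raster, b.raster)


class TestIdenticalNeurons:
    def test_identical_pair_follows_identical_trajectories(self):
        # two neurons with the same window, phase and action stream lie on
        # the identical synchronisation manifold for every t
        cfg = SimulationConfig(n_neurons=2, n_steps=150, t_max_low=18,
                               t_max_high=18, phase_spread=0,
                               structure_seed=0, action_seed=0)
        net = Network(cfg)
        net._rngs = [np.random.default_rng(42), np.random.default_rng(42)]
        res = net.run()
        assert np.array_equal(res.fired[:, 0], res.fired[:, 1])
        assert np.array_equal(res.raster[:, 0], res.raster[:, 1])
        assert np.allclose(res.firing_prob[:, 0], res.firing_prob[:, 1])


class TestUncoupledEqualsIsolated:
    def test_zero_precision_network_matches_single_neuron_runs(self):
        n, steps = 4, 200
        cfg = SimulationConfig(n_neurons=n, n_steps=steps, initial_zeta=0.0,
                               phase_spread=20, structure_seed=8,
                               action_seed=8)
        res = run_experiment(cfg)
        for i in range(n):
            solo = SimulationConfig(
                n_neurons=1, n_steps=steps, initial_zeta=0.0,
                phase_spread=20, structure_seed=8, action_seed=8,
                neuron_id_offset=i,
            )
            solo_res = run_experiment(solo)
            assert np.array_equal(res.fired[:, i], solo_res.fired[:, 0])
            assert np.array_equal(res.raster[:, i], solo_res.raster[:, 0])
            assert np.allclose(res.firing_prob[:, i],
                               solo_res.firing_prob[:, 0])


class TestEngineMatchesPublicOperations:
    def test_vectorised_step_equals_per_neuron_inference(self):
        """Re-simulate a small network with the scalar public operations
        (build_transition / update_belief / compute_free_energy /
        fired_from_belief) and compare against the vectorised engine."""
        cfg = SimulationConfig(
            n_neurons=3, n_steps=60, phase_spread=10,
            structure_seed=5, action_seed=5,
            protocols=(StimulusProtocol(targets=(1,), onset=20, offset=24),),
        )
        res = run_experiment(cfg)

        net = Network(cfg)  # fresh instance for structure + initial history
        n, pad = cfg.n_neurons, net.pad
        f = cfg.transition_floor
        base = np.asarray(cfg.base_table)
        abar = normalize_likelihood(base, cfg.initial_zeta)
        hist = [list(net.hist[:pad, i]) for i in range(n)]
        rngs = [np.random.default_rng([cfg.action_seed, 11, i])
                for i in range(n)]
        beliefs = [Belief(np.zeros(2)) for _ in range(n)]
        prev_spikes = np.zeros(n, dtype=int)

        for t in range(1, cfg.n_steps + 1):
            new_beliefs, new_spikes = [], []
            for i in range(n):
                others = [j for j in range(n) if j != i]
                obs = np.array([prev_spikes[j] for j in others])
                for proto in cfg.protocols:
                    obs = apply_stimulus(obs, proto, i, t)
                window = OscillatorWindow(t_min=cfg.t_min,
                                          t_max=int(net.t_max[i]))
                b = build_transition(hist[i], pad + t, window)
                b_floored = np.where(b == 0.0, f, 1.0 - f)
                liks = [(abar, cfg.initial_zeta)] * len(others)
                belief = update_belief(
                    beliefs[i], obs, liks, b_floored, Belief(np.zeros(2)),
                    step=cfg.belief_step, n_iter=cfg.belief_iters,
                    tol=cfg.belief_tol,
                )
                fe = compute_free_energy(belief, obs, liks, b_floored,
                                         Belief(np.zeros(2)))
                assert belief.firing_expectation == pytest.approx(
                    res.firing_prob[t - 1, i], abs=1e-6)
                assert fe == pytest.approx(res.free_energy[t - 1, i],
                                           abs=1e-6)
                fired = fired_from_belief(belief.firing_expectation)
                assert fired == res.fired[t - 1, i]
                hist[i].append(fired)
                spike = int(rngs[i].random() < belief.firing_expectation)
                assert spike == res.raster[t - 1, i]
                new_beliefs.append(belief)
                new_spikes.append(spike)
            beliefs = new_beliefs
            prev_spikes = np.array(new_spikes)


class TestApplyStimulus:
    proto = StimulusProtocol(targets=(2,), onset=10, offset=13)

    def test_non_target_unchanged(self):
        obs = np.array([0, 1, 0])
        assert np.array_equal(apply_stimulus(obs, self.proto, 1, 11), obs)

    def test_target_during_pulse_gets_all_ones(self):
        obs = np.zeros(5, dtype=int)
        out = apply_stimulus(obs, self.proto, 2, 12)
        assert np.all(out == 1)

    def test_half_open_interval(self):
        obs = np.zeros(3, dtype=int)
        assert np.array_equal(apply_stimulus(obs, self.proto, 2, 13), obs)
        assert np.array_equal(apply_stimulus(obs, self.proto, 2, 9), obs)

    def test_sustained_square_wave_phase(self):
        p = StimulusProtocol(targets=(0,), onset=0, offset=100,
                             mode="sustained", period=10, on_steps=5, phase=0)
        on = [p.active_at(t, 0) for t in range(20)]
        assert on[:5] == [True] * 5 and on[5:10] == [False] * 5


class TestConfigValidation:
    def test_invalid_protocol_targets_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                n_neurons=4,
                protocols=(StimulusProtocol(targets=(7,), onset=1, offset=2),),
            )

    def test_window_bound_violation_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(t_min=20, t_max_low=10, t_max_high=15)

    def test_run_experiment_requires_config(self):
        with pytest.raises(ConfigError):
            run_experiment({"n_neurons": 4})


class TestNetworkStructure:
    def test_fully_connected_without_self_synapses(self):
        net = Network(fepnet.synchrony_config(seed=0))
        assert net.active.sum() == 16 * 15
        assert not np.any(np.diag(net.active))
        neuron = net.neuron(0)
        assert 0 not in neuron.synapses
        assert len(neuron.synapses) == 15

    def test_no_runaway_firing(self):
        # bounded duty cycle in every stock experiment: spike counts stay
        # far from saturation under the clamped precision
        for cfg in (fepnet.synchrony_config(seed=1, n_steps=300),
                    fepnet.perturbation_config(seed=1, n_steps=250)):
            res = run_experiment(cfg)
            for start in range(0, cfg.n_steps - 100, 100):
                counts = res.raster[start:start + 100].sum(axis=0)
                assert counts.max() <= 60

    def test_pruning_is_irreversible_and_monotone(self):
        res = run_experiment(fepnet.structure_config(seed=0, n_steps=400))
        sizes = [a.sum() for a in res.adjacency]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))
        for t, i, j, df in res.pruning_log:
            assert df > res.config.pruning_threshold
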