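"""Network orchestration: time stepping, spike exchange, stimulation,
plasticity periods and pruning epochs.

The generative *process* is synchronous with a one-step delay: a spike
emitted at step ``t`` is the observation of every efferent target at
``t + 1``.  Within a step each neuron (i) assembles its observation vector
from the previous step's spikes, restricted to its active synapses and
overridden by any active stimulation protocol; (ii) builds its transition
message from its own thresholded firing history; (iii) relaxes its belief by
gradient flow on free energy; (iv) records the step free energy; and (v)
draws a spike from a Bernoulli with its firing expectation.

Plasticity accumulates the per-synapse precision gradient every step and
applies a damped update of the gamma posterior once per period.  Pruning
runs once per epoch: the evidence accumulated over the epoch is folded into
the posterior rate (the undamped variational solution) and each active
synapse is retained or removed by Bayesian model reduction; removal is
irreversible.

The inner loops are vectorised across neurons; the per-neuron semantics are
exactly those of the public operations in :mod:`fepnet.inference`,
:mod:`fepnet.plasticity` and :mod:`fepnet.pruning` (the test suite checks
this equivalence on small networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import SimulationConfig, StimulusProtocol  # noqa: F401 (re-export)
from .exceptions import ConfigError
from .generative_model import GammaBelief, LikelihoodBase, OscillatorWindow
from .inference import LOG_FLOOR, Belief, FreeEnergyTrace
from .metrics import BurstTrain, detect_bursts, order_parameter_trace
from .plasticity import POSTERIOR_RATE_FLOOR

__all__ = [
    "NeuronModel",
    "SynapseModel",
    "SimulationResult",
    "Network",
    "run_experiment",
    "apply_stimulus",
]


@dataclass
class SynapseModel:
    """One afferent connection as seen by its postsynaptic neuron."""

    pre_id: int
    base: LikelihoodBase
    gamma: GammaBelief
    active: bool = True


@dataclass
class NeuronModel:
    """Snapshot view of a single agent in the network."""

    id: int
    initial_state_prior: np.ndarray
    window: OscillatorWindow
    belief: Belief
    fired_history: np.ndarray
    synapses: dict[int, SynapseModel]


@dataclass
class SimulationResult:
    """Everything a simulation produces, on the integer step grid.

    Arrays are indexed ``[step, neuron]`` (0-based step ``k`` holds
    simulation step ``k + 1``).  ``fired`` is the thresholded-belief train
    that drives the intrinsic oscillator; ``raster`` is the Bernoulli spike
    train actually transmitted.  ``zeta_traj`` holds the expected precision
    matrix after each plasticity period; ``adjacency`` the active-synapse
    matrix after each pruning epoch (entry ``[i, j]`` is the synapse from
    ``j`` to ``i``).
    """

    config: SimulationConfig
    raster: np.ndarray
    fired: np.ndarray
    firing_prob: np.ndarray
    potential: np.ndarray
    free_energy: np.ndarray
    zeta_traj: np.ndarray          # (n_periods, n, n)
    zeta_times: np.ndarray         # step at which each snapshot was taken
    adjacency: np.ndarray          # (n_epochs + 1, n, n) incl. initial state
    adjacency_times: np.ndarray
    #: per-epoch log Bayes factors for removing each active synapse
    #: (NaN for already-inactive synapses); shape (n_epochs, n, n)
    reduction_traces: np.ndarray
    final_zeta: np.ndarray
    final_active: np.ndarray
    windows: np.ndarray            # per-neuron t_max
    pruning_log: list = field(default_factory=list)

    # -- convenience views -------------------------------------------------
    def burst_trains(self, source: str = "fired", max_gap: int = 2
                     ) -> list[BurstTrain]:
        """Per-neuron burst trains from the thresholded-belief train
        (``"fired"``, the model's definition of having fired) or from the
        transmitted spikes (``"raster"``)."""
        data = {"fired": self.fired, "raster": self.raster}[source]
        return [detect_bursts(data[:, i], max_gap=max_gap)
                for i in range(data.shape[1])]

    def order_trace(self, source: str = "fired") -> np.ndarray:
        return order_parameter_trace(self.burst_trains(source),
                                     self.config.n_steps)

    def free_energy_trace(self) -> FreeEnergyTrace:
        return FreeEnergyTrace(self.free_energy)

    def mean_active_zeta(self) -> float:
        """Mean expected precision over the surviving synapses."""
        if not self.final_active.any():
            return float("nan")
        return float(self.final_zeta[self.final_active].mean())


def apply_stimulus(
    obs: np.ndarray,
    protocol: StimulusProtocol,
    neuron_id: int,
    t: int,
) -> np.ndarray:
    """Forced-observation override for one neuron at step ``t``.

    If the protocol targets the neuron and is active at ``t``, every entry
    of the observation vector is replaced by the protocol's value;
    otherwise the observation is returned unchanged.
    """
    if protocol.active_at(t, neuron_id):
        return np.full_like(np.asarray(obs), protocol.value)
    return np.asarray(obs)


class Network:
    """Mutable simulation state for one network run."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        n = config.n_neurons
        self.n = n

        # structural draws: per-neuron seeded so that a one-neuron network
        # with neuron_id_offset=i reproduces neuron i of a larger network
        self.t_max = np.empty(n, dtype=int)
        phase = np.empty(n, dtype=int)
        for i in range(n):
            rng = np.random.default_rng(
                [config.structure_seed, 7, config.neuron_id_offset + i])
            self.t_max[i] = rng.integers(config.t_max_low,
                                         config.t_max_high + 1)
            phase[i] = (rng.integers(0, config.phase_spread + 1)
                        if config.phase_spread > 0 else 0)
        self.t_min = config.t_min

        # firing history with padding holding one synthetic pre-burst per
        # neuron; the pre-burst end is placed phase steps into the cycle, so
        # the first intrinsic onset falls at step end + t_max + 1
        self.pad = int(config.t_max_high + 2 * config.t_min)
        self.hist = np.zeros((self.pad + config.n_steps, n), dtype=np.int8)
        for i in range(n):
            cycle = int(self.t_max[i]) + self.t_min
            end = -(int(phase[i]) % cycle)  # burst end step (<= 0)
            for s in range(end - self.t_min + 1, end + 1):
                row = self.pad + s - 1
                if 0 <= row < self.pad:
                    self.hist[row, i] = 1

        # synapses: full connectivity without self-connections
        self.active = ~np.eye(n, dtype=bool)
        self.base = np.asarray(config.base_table, dtype=float)
        self.log_base = np.log(self.base)
        self.beta_prior = np.full((n, n),
                                  np.inf if config.initial_zeta == 0
                                  else 1.0 / config.initial_zeta)
        self.beta_post = self.beta_prior.copy()
        self.zeta = np.full((n, n), config.initial_zeta)

        self._refresh_synapse_tables()

        # belief state: start from the uniform potential
        self.upsilon = np.zeros((n, 2))

        # transition log-message templates
        f = config.transition_floor
        self._b_fire = np.log(np.array([f, 1.0 - f]))
        self._b_silent = np.log(np.array([1.0 - f, f]))

        # rngs for action sampling, one independent stream per neuron
        self._rngs = [
            np.random.default_rng(
                [config.action_seed, 11, config.neuron_id_offset + i])
            for i in range(n)
        ]

        # plasticity / pruning accumulators
        self._acc_period = np.zeros((n, n))
        self._acc_epoch = np.zeros((n, n))

        self.t = 0
        self._prev_spikes = np.zeros(n, dtype=np.int8)

        # records
        ns = config.n_steps
        self.raster = np.zeros((ns, n), dtype=np.int8)
        self.fired = np.zeros((ns, n), dtype=np.int8)
        self.firing_prob = np.zeros((ns, n))
        self.potential = np.zeros((ns, n))
        self.free_energy = np.zeros((ns, n))
        self._zeta_snaps: list[np.ndarray] = []
        self._zeta_times: list[int] = []
        self._adj_snaps: list[np.ndarray] = [self.active.copy()]
        self._adj_times: list[int] = [0]
        self._df_snaps: list[np.ndarray] = []
        self.pruning_log: list[tuple[int, int, int, float]] = []

    # ------------------------------------------------------------------
    def _refresh_synapse_tables(self) -> None:
        """Recompute per-synapse message weights and gradient tables from
        the current precision matrix (called whenever zeta changes)."""
        z = self.zeta[..., None, None]                      # (n, n, 1, 1)
        logw = z * self.log_base                            # (n, n, 2, 2)
        logw = logw - logw.max(axis=2, keepdims=True)
        w = np.exp(logw)
        abar = w / w.sum(axis=2, keepdims=True)             # normalised A
        log_abar = np.log(np.maximum(abar, LOG_FLOOR))
        # message weights W[i, j, o, h] = zeta_ij * ln Abar_ij[o, h]
        self._W = self.zeta[:, :, None, None] * log_abar
        # gradient tables: D[o][i, j, h] = ln A[:, h] . (onehot(o) - Abar[:, h])
        onehot = np.eye(2)
        # (n, n, o, h): sum over rows r of log_base[r, h] * (onehot[o, r] - abar[r, h])
        self._D = np.einsum(
            "rh,orijh->ijoh",
            self.log_base,
            onehot[:, :, None, None, None] - abar.transpose(2, 0, 1, 3)[None],
        )

    # ------------------------------------------------------------------
    def _transition_messages(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron forward log message and predicted-firing flag from the
        oscillator window {t - t_max, ..., t - t_min} of the own history."""
        msgs = np.empty((self.n, 2))
        fire_pred = np.empty(self.n, dtype=bool)
        for i in range(self.n):
            lo = self.pad + t - int(self.t_max[i]) - 1
            hi = self.pad + t - self.t_min  # slice end (exclusive)
            quiet = not np.any(self.hist[max(lo, 0):max(hi, 0), i])
            fire_pred[i] = quiet
            msgs[i] = self._b_fire if quiet else self._b_silent
        return msgs, fire_pred

    def _observations(self, t: int) -> np.ndarray:
        """Observation matrix obs[i, j] = spike of j at t-1, with
        observation-action stimulus overrides applied per target neuron."""
        obs = np.broadcast_to(self._prev_spikes, (self.n, self.n)).copy()
        for proto in self.config.protocols:
            if proto.action != "observations":
                continue
            for i in proto.targets:
                if proto.active_at(t, i):
                    obs[i, :] = proto.value
        return obs

    def _injected_current(self, t: int) -> np.ndarray:
        """Depolarising message from current-action protocols: a 2-vector
        per neuron added to the summed log messages during belief updating
        (but not to the generative model's free energy)."""
        inj = np.zeros((self.n, 2))
        for proto in self.config.protocols:
            if proto.action != "current":
                continue
            push = proto.gain * (0.5 if proto.value == 1 else -0.5)
            for i in proto.targets:
                if proto.active_at(t, i):
                    inj[i] += (-push, push)
        return inj

    # ------------------------------------------------------------------
    def step(self) -> None:
        """Advance the whole network by one time step."""
        cfg = self.config
        self.t += 1
        t = self.t
        k = t - 1  # record row

        obs = self._observations(t)
        b_msg, _ = self._transition_messages(t)

        # summed messages per neuron: active-synapse likelihoods + forward
        Wsel = np.take_along_axis(
            self._W, obs[:, :, None, None].astype(int), axis=2
        )[:, :, 0, :]                                      # (n, n, 2)
        m = (Wsel * self.active[:, :, None]).sum(axis=1) + b_msg
        m_drive = m + self._injected_current(t)

        # belief gradient flow (vectorised fepnet.inference.update_belief)
        ups = self.upsilon
        for _ in range(cfg.belief_iters):
            logs = ups - ups.max(axis=1, keepdims=True)
            logs = logs - np.log(np.exp(logs).sum(axis=1, keepdims=True))
            eps = np.maximum(logs, np.log(LOG_FLOOR)) - m_drive
            eps = eps - eps.mean(axis=1, keepdims=True)
            if np.abs(eps).max() < cfg.belief_tol:
                break
            ups = ups - cfg.belief_step * eps
        self.upsilon = ups - ups.mean(axis=1, keepdims=True)

        probs = np.exp(self.upsilon
                       - self.upsilon.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)

        # step free energy: s . (ln s - m)
        log_s = np.log(np.maximum(probs, LOG_FLOOR))
        self.free_energy[k] = np.sum(probs * (log_s - m), axis=1)

        # record, threshold, act
        p_fire = probs[:, 1]
        self.firing_prob[k] = p_fire
        self.potential[k] = self.upsilon[:, 1] - self.upsilon[:, 0]
        fired = (p_fire > 0.5).astype(np.int8)
        self.fired[k] = fired
        self.hist[self.pad + k] = fired
        spikes = np.array(
            [self._rngs[i].random() < p_fire[i] for i in range(self.n)],
            dtype=np.int8,
        )
        self.raster[k] = spikes
        self._prev_spikes = spikes

        # plasticity: accumulate the precision gradient for active synapses
        if cfg.plasticity_enabled or cfg.pruning_enabled:
            Dsel = np.take_along_axis(
                self._D, obs[:, :, None, None].astype(int), axis=2
            )[:, :, 0, :]                                  # (n, n, h)
            g = (Dsel * probs[:, None, :]).sum(axis=2) * self.active
            self._acc_period += g
            self._acc_epoch += g

        if cfg.plasticity_enabled:
            if t % cfg.plasticity_period == 0:
                G = self._acc_period.copy()
                self._acc_period[:] = 0.0
                err = self.beta_prior - G - self.beta_post
                self.beta_post = self.beta_post + cfg.plasticity_rate * err
                floor = max(POSTERIOR_RATE_FLOOR,
                            np.nextafter(1.0 / cfg.zeta_max, np.inf))
                np.clip(self.beta_post, floor, None, out=self.beta_post)
                self.zeta = np.where(self.active, 1.0 / self.beta_post, 0.0)
                self._refresh_synapse_tables()
                self._zeta_snaps.append(self.zeta.copy())
                self._zeta_times.append(t)

        # pruning: Bayesian model reduction on the epoch-evidence posterior
        if cfg.pruning_enabled and t % cfg.epoch_length == 0:
            acc = self._acc_epoch.copy()
            self._acc_epoch[:] = 0.0
            beta_eval = np.maximum(self.beta_post - acc, POSTERIOR_RATE_FLOOR)
            denom = beta_eval - self.beta_prior + cfg.reduced_rate
            with np.errstate(divide="ignore", invalid="ignore"):
                df = (np.log(cfg.reduced_rate) - np.log(self.beta_prior)
                      + np.log(beta_eval) - np.log(np.maximum(denom, 1e-300)))
            df = np.where(denom > 0, df, -np.inf)
            self._df_snaps.append(np.where(self.active, df, np.nan))
            newly = self.active & (df > cfg.pruning_threshold)
            if newly.any():
                for i, j in zip(*np.nonzero(newly)):
                    self.pruning_log.append((t, int(i), int(j),
                                             float(df[i, j])))
                self.active &= ~newly
                self.zeta = np.where(self.active, self.zeta, 0.0)
            self._adj_snaps.append(self.active.copy())
            self._adj_times.append(t)

    # ------------------------------------------------------------------
    def run(self) -> SimulationResult:
        for _ in range(self.config.n_steps):
            self.step()
        return SimulationResult(
            config=self.config,
            raster=self.raster,
            fired=self.fired,
            firing_prob=self.firing_prob,
            potential=self.potential,
            free_energy=self.free_energy,
            zeta_traj=(np.array(self._zeta_snaps)
                       if self._zeta_snaps else np.zeros((0, self.n, self.n))),
            zeta_times=np.array(self._zeta_times, dtype=int),
            adjacency=np.array(self._adj_snaps),
            adjacency_times=np.array(self._adj_times, dtype=int),
            reduction_traces=(np.array(self._df_snaps) if self._df_snaps
                              else np.zeros((0, self.n, self.n))),
            final_zeta=self.zeta.copy(),
            final_active=self.active.copy(),
            windows=self.t_max.copy(),
            pruning_log=list(self.pruning_log),
        )

    # ------------------------------------------------------------------
    def neuron(self, i: int) -> NeuronModel:
        """Object view of one neuron (for inspection and small-scale tests)."""
        synapses = {
            j: SynapseModel(
                pre_id=j,
                base=LikelihoodBase(self.base),
                gamma=GammaBelief(
                    prior_rate=float(self.beta_prior[i, j]),
                    posterior_rate=float(self.beta_post[i, j]),
                ) if np.isfinite(self.beta_post[i, j]) else None,
                active=bool(self.active[i, j]),
            )
            for j in range(self.n) if j != i
        }
        return NeuronModel(
            id=i,
            initial_state_prior=np.array([0.5, 0.5]),
            window=OscillatorWindow(t_min=self.t_min, t_max=int(self.t_max[i])),
            belief=Belief(self.upsilon[i].copy()),
            fired_history=self.hist[: self.pad + self.t, i].copy(),
            synapses=synapses,
        )


def run_experiment(config: SimulationConfig) -> SimulationResult:
    """Build a network from a configuration and run it to completion.

    Deterministic given the configuration's seeds: repeated calls return
    bit-identical results.
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigError("run_experiment expects a SimulationConfig")
    return Network(config).run()
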