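"""Simulation configuration: defaults, validation and (de)serialisation.

The default values encode the study conditions of the three stock
experiments: a fully connected network of 16 neurons on a 2 ms grid, initial
synaptic precision 0.5 (gamma prior rate 2), intrinsic inter-burst onset
intervals of 40-60 ms (window t_max drawn per neuron from 15-25 steps with
t_min = 5), plasticity accumulated over 25-step periods, pruning evaluated
over 50-step epochs at a log-Bayes-factor threshold of 2.5.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, replace
from typing import Any, Literal

import numpy as np
import yaml

from .exceptions import ConfigError

__all__ = [
    "StimulusProtocol",
    "SimulationConfig",
    "load_config",
    "dump_config",
    "synchrony_config",
    "perturbation_config",
    "structure_config",
]

#: Default unnormalised likelihood table shared by every synapse.
#: Rows = observation (no EPSP / EPSP), columns = network state
#: (silent / firing).  The table is deliberately asymmetric: an EPSP is
#: strong evidence that the network is firing, whereas silence is only weak
#: evidence of a silent network (any individual afferent neuron spikes
#: stochastically even when the ensemble is active).  See docs/methods.md
#: for the calibration of these values.
DEFAULT_BASE_TABLE = ((0.70, 0.25), (0.30, 0.75))

#: Pseudo-probability assigned to the zero entries of the deterministic
#: transition matrix when forming its log message.  This is the precision of
#: the intrinsic rhythm relative to synaptic evidence: 0 makes the oscillator
#: infinitely stubborn, 0.5 removes it entirely.
DEFAULT_TRANSITION_FLOOR = 0.1


@dataclass(frozen=True)
class StimulusProtocol:
    """External stimulation of a set of target neurons.

    While active, the stimulus either forces every afferent observation of
    a targeted neuron to ``value`` (``action="observations"``: spoofed
    EPSPs) or injects a depolarising/hyperpolarising current into the
    belief update while the real observations stay visible
    (``action="current"``).  ``pulse`` mode is active throughout
    ``[onset, offset)``; ``sustained`` mode gates the stimulus with a
    square wave of the given ``period``/``on_steps``/``phase`` (in steps),
    so two protocols with phases half a period apart deliver asynchronous
    input to two populations.
    """

    targets: tuple[int, ...]
    onset: int
    offset: int
    mode: Literal["pulse", "sustained"] = "pulse"
    value: int = 1
    period: int = 50
    on_steps: int = 25
    phase: int = 0
    #: how the stimulus reaches the neuron: ``"observations"`` overwrites
    #: every afferent observation with ``value`` (spoofed EPSPs);
    #: ``"current"`` injects a depolarising message of size ``gain`` into
    #: the belief update while the real observations remain visible
    action: Literal["observations", "current"] = "observations"
    gain: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(int(t) for t in self.targets))
        if self.onset >= self.offset:
            raise ConfigError("protocol onset must precede offset")
        if self.mode not in ("pulse", "sustained"):
            raise ConfigError(f"unknown stimulus mode {self.mode!r}")
        if self.value not in (0, 1):
            raise ConfigError("forced observation value must be 0 or 1")
        if self.mode == "sustained" and not (0 < self.on_steps <= self.period):
            raise ConfigError("sustained mode needs 0 < on_steps <= period")
        if self.action not in ("observations", "current"):
            raise ConfigError(f"unknown stimulus action {self.action!r}")
        if self.gain <= 0:
            raise ConfigError("stimulus gain must be positive")

    def active_at(self, t: int, neuron_id: int) -> bool:
        """Is the forcing applied to this neuron at (1-based) step ``t``?"""
        if neuron_id not in self.targets or not (self.onset <= t < self.offset):
            return False
        if self.mode == "pulse":
            return True
        return ((t - self.onset + self.phase) % self.period) < self.on_steps


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one network simulation."""

    # network / timing
    n_neurons: int = 16
    n_steps: int = 500
    dt_ms: float = 2.0
    # generative model
    t_min: int = 5
    t_max_low: int = 15          # inclusive lower bound of per-neuron t_max
    t_max_high: int = 25         # inclusive upper bound
    base_table: tuple = DEFAULT_BASE_TABLE
    transition_floor: float = DEFAULT_TRANSITION_FLOOR
    initial_zeta: float = 0.5
    # inference
    belief_step: float = 0.25
    belief_iters: int = 16
    belief_tol: float = 1e-6
    # plasticity
    plasticity_enabled: bool = False
    plasticity_period: int = 25
    plasticity_rate: float = 1e-2
    zeta_max: float = 0.95
    # pruning
    pruning_enabled: bool = False
    epoch_length: int = 50
    pruning_threshold: float = 2.5
    reduced_rate: float = 400.0
    # stimulation
    protocols: tuple[StimulusProtocol, ...] = ()
    # initial phases: per-neuron phase offset drawn uniformly from
    # {0, ..., phase_spread} (modulo the neuron's own cycle length);
    # 0 = all neurons start in phase
    phase_spread: int = 0
    # reporting
    fe_window: int = 15
    # seeding
    structure_seed: int = 0
    action_seed: int = 0
    neuron_id_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "protocols", tuple(self.protocols) if self.protocols else ()
        )
        base = np.asarray(self.base_table, dtype=float)
        if base.shape != (2, 2) or not np.all(base > 0):
            raise ConfigError(
                "base_table must be a strictly positive 2x2 table"
            )
        object.__setattr__(
            self, "base_table",
            tuple(tuple(float(x) for x in row) for row in base),
        )
        self.validate()

    def validate(self) -> None:
        c = self
        if c.n_neurons < 1:
            raise ConfigError("n_neurons must be >= 1")
        if c.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if c.dt_ms <= 0:
            raise ConfigError("dt_ms must be positive")
        if not (1 <= c.t_min < c.t_max_low <= c.t_max_high):
            raise ConfigError(
                "window bounds must satisfy 1 <= t_min < t_max_low <= "
                "t_max_high"
            )
        if not (0.0 < c.transition_floor < 0.5):
            raise ConfigError("transition_floor must lie in (0, 0.5)")
        if c.initial_zeta < 0:
            raise ConfigError("initial_zeta must be >= 0")
        if c.initial_zeta == 0 and (c.plasticity_enabled or c.pruning_enabled):
            raise ConfigError(
                "plasticity and pruning require strictly positive initial_zeta"
            )
        if c.belief_step <= 0 or c.belief_iters < 1:
            raise ConfigError("belief_step must be > 0 and belief_iters >= 1")
        if c.plasticity_period < 1 or c.epoch_length < 1:
            raise ConfigError("plasticity_period and epoch_length must be >= 1")
        if c.plasticity_rate <= 0:
            raise ConfigError("plasticity_rate must be positive")
        if not (0 < c.zeta_max <= 1):
            raise ConfigError("zeta_max must lie in (0, 1]")
        if c.reduced_rate <= 0:
            raise ConfigError("reduced_rate must be positive")
        if c.phase_spread < 0:
            raise ConfigError("phase_spread must be >= 0")
        if c.fe_window < 1:
            raise ConfigError("fe_window must be >= 1")
        for p in c.protocols:
            bad = [t for t in p.targets if not (0 <= t < c.n_neurons)]
            if bad:
                raise ConfigError(f"protocol targets {bad} are not valid ids")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        protos = []
        for p in self.protocols:
            pd = asdict(p)
            pd["targets"] = list(pd["targets"])
            protos.append(pd)
        d["protocols"] = protos
        d["base_table"] = [list(row) for row in self.base_table]
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = [k for k in data if k not in known]
        if unknown:
            hints = []
            for k in unknown:
                match = difflib.get_close_matches(k, known, n=1)
                hints.append(f"{k!r}" + (f" (did you mean {match[0]!r}?)"
                                         if match else ""))
            raise ConfigError("unknown config keys: " + ", ".join(hints))
        data = dict(data)
        if "protocols" in data:
            data["protocols"] = tuple(
                p if isinstance(p, StimulusProtocol)
                else StimulusProtocol(**{**p, "targets": tuple(p["targets"])})
                for p in data["protocols"]
            )
        if "base_table" in data:
            data["base_table"] = tuple(
                tuple(row) for row in data["base_table"]
            )
        return cls(**data)

    def replace(self, **changes: Any) -> "SimulationConfig":
        return replace(self, **changes)


def load_config(path: str) -> SimulationConfig:
    """Read a YAML configuration file; absent keys take the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return SimulationConfig.from_dict(data)


def dump_config(config: SimulationConfig, path: str) -> None:
    """Write a configuration as YAML (round-trips through load_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stock experiment configurations


def synchrony_config(
    seed: int = 0, coupled: bool = True, n_steps: int = 500, **overrides: Any
) -> SimulationConfig:
    """Fig-4-style run: free-running network, coupled or uncoupled.

    The uncoupled condition sets every synaptic precision to zero, leaving
    each neuron to its intrinsic oscillation.  Neurons start with random
    relative phases across a full cycle.
    """
    return SimulationConfig(
        n_steps=n_steps,
        initial_zeta=0.5 if coupled else 0.0,
        phase_spread=30,
        structure_seed=seed,
        action_seed=seed,
        **overrides,
    )


def perturbation_config(
    seed: int = 0, n_steps: int = 250, **overrides: Any
) -> SimulationConfig:
    """Fig-5-style run: two pulses to half the ensemble, plasticity on.

    The network starts synchronised (small phase spread); 3-step pulses
    force all observations of neurons 0-7 to 1 near steps 50 and 75.
    """
    half = tuple(range(8))
    return SimulationConfig(
        n_steps=n_steps,
        plasticity_enabled=True,
        phase_spread=2,
        protocols=(
            StimulusProtocol(targets=half, onset=50, offset=53, mode="pulse"),
            StimulusProtocol(targets=half, onset=75, offset=78, mode="pulse"),
        ),
        fe_window=15,
        structure_seed=seed,
        action_seed=seed,
        **overrides,
    )


def structure_config(
    seed: int = 0, n_steps: int = 1200, **overrides: Any
) -> SimulationConfig:
    """Fig-6-style run: two pools under asynchronous sustained input.

    Pools {0..7} and {8..15} receive antiphase square-wave forcing from the
    start of epoch 3 to the end of epoch 20 (steps 100-1000 at the default
    50-step epoch); plasticity and pruning are both active.
    """
    pool_a = tuple(range(8))
    pool_b = tuple(range(8, 16))
    return SimulationConfig(
        n_steps=n_steps,
        plasticity_enabled=True,
        pruning_enabled=True,
        phase_spread=2,
        protocols=(
            # pool A: depolarised for one half-cycle, hyperpolarised for the
            # other; pool B the same with opposite phase, so the two pools
            # are driven into antiphase firing
            StimulusProtocol(targets=pool_a, onset=100, offset=1000,
                             mode="sustained", period=50, on_steps=25,
                             phase=0, action="current", value=1),
            StimulusProtocol(targets=pool_a, onset=100, offset=1000,
                             mode="sustained", period=50, on_steps=25,
                             phase=25, action="current", value=0),
            StimulusProtocol(targets=pool_b, onset=100, offset=1000,
                             mode="sustained", period=50, on_steps=25,
                             phase=25, action="current", value=1),
            StimulusProtocol(targets=pool_b, onset=100, offset=1000,
                             mode="sustained", period=50, on_steps=25,
                             phase=0, action="current", value=0),
        ),
        fe_window=35,
        structure_seed=seed,
        action_seed=seed,
        **overrides,
    )
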