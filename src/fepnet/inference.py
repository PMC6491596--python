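"""Belief updating by gradient flow on variational free energy.

Each time step a neuron combines two kinds of message about the hidden
network state: per-synapse likelihood messages ``zeta_i * ln Abar_i[o_i, :]``
(evidence from the EPSP pattern) and the forward transition message
``ln(B_prev @ s_prev)`` (its own oscillatory prediction).  The log
expectation ``upsilon`` (the somatic potential) follows the negative
prediction error,

    d(upsilon)/dt = -eps,    eps = ln s - (sum_i zeta_i ln Abar_i . o_i
                                           + ln(B_prev s_prev)),

with ``s = softmax(upsilon)``; the fixed point is the softmax of the summed
messages.  The postdiction (backward) message is omitted throughout, as it
plays no role without a model of future policies.

Free energy is evaluated per time step as ``s . (ln s - m)`` where ``m`` is
the summed message, which equals the step-specific variational free energy
of the two-state model and upper-bounds the negative log evidence of the
observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ContractError, DomainError

__all__ = [
    "LOG_FLOOR",
    "Belief",
    "Observation",
    "FreeEnergyTrace",
    "log_messages",
    "prediction_error",
    "update_belief",
    "compute_free_energy",
    "sample_action",
]

#: Numerical floor applied inside logarithms of probabilities.
LOG_FLOOR = 1e-16


def _softmax(v: np.ndarray) -> np.ndarray:
    v = v - v.max()
    e = np.exp(v)
    return e / e.sum()


def _flog(p: np.ndarray, floor: float = LOG_FLOOR) -> np.ndarray:
    return np.log(np.maximum(p, floor))


@dataclass(frozen=True)
class Belief:
    """Posterior belief over the binary network state.

    ``potential`` is the pre-softmax log expectation (the somatic voltage);
    ``probs`` is always its softmax, so the belief lives on the simplex by
    construction.
    """

    potential: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        pot = np.asarray(self.potential, dtype=float)
        if pot.shape != (2,) or not np.all(np.isfinite(pot)):
            raise ContractError("potential must be a finite 2-vector")
        object.__setattr__(self, "potential", pot)

    @classmethod
    def from_probs(cls, probs: Sequence[float]) -> "Belief":
        p = np.asarray(probs, dtype=float)
        if p.shape != (2,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ContractError("probs must be a 2-vector on the simplex")
        return cls(_flog(p))

    @property
    def probs(self) -> np.ndarray:
        return _softmax(self.potential)

    @property
    def firing_expectation(self) -> float:
        """Probability assigned to the 'network firing' state."""
        return float(self.probs[1])


@dataclass(frozen=True)
class Observation:
    """Binary EPSP pattern across the afferent synapses of one neuron."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        if v.ndim != 1 or not np.all((v == 0) | (v == 1)):
            raise ContractError("observation entries must be binary")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def log_messages(
    obs: Observation | Sequence[int],
    likelihoods: Sequence[tuple[np.ndarray, float]],
    B_prev: np.ndarray,
    prev_belief: Belief,
    floor: float = LOG_FLOOR,
) -> np.ndarray:
    """Summed log messages about the current state (likelihood + forward).

    ``likelihoods`` is one ``(Abar, zeta)`` pair per afferent synapse, where
    ``Abar`` is the already-normalised 2x2 likelihood.  Returns the 2-vector
    ``sum_i zeta_i ln Abar_i[o_i, :] + ln(B_prev @ s_prev)``.
    """
    if not isinstance(obs, Observation):
        obs = Observation(np.asarray(obs))
    if len(obs) != len(likelihoods):
        raise ContractError(
            f"observation length {len(obs)} != number of synapses "
            f"{len(likelihoods)}"
        )
    m = np.zeros(2)
    for o, (abar, zeta) in zip(obs.values, likelihoods):
        if zeta < 0:
            raise DomainError("synaptic precision must be >= 0")
        if zeta == 0.0:
            continue  # uninformative synapse contributes exactly nothing
        m += zeta * _flog(np.asarray(abar)[int(o), :], floor)
    m += _flog(np.asarray(B_prev) @ prev_belief.probs, floor)
    return m


def prediction_error(
    belief: Belief,
    obs: Observation | Sequence[int],
    likelihoods: Sequence[tuple[np.ndarray, float]],
    B_prev: np.ndarray,
    prev_belief: Belief,
    floor: float = LOG_FLOOR,
) -> np.ndarray:
    """State prediction error ``eps = ln s - m``.

    Zero exactly when the belief equals the softmax of the summed messages
    (``ln s`` and ``m`` then differ by a constant that the comparison against
    the mean removes: the error is reported mean-centred so that the
    zero-at-fixed-point property is exact on the simplex).
    """
    m = log_messages(obs, likelihoods, B_prev, prev_belief, floor)
    eps = _flog(belief.probs, floor) - m
    return eps - eps.mean()


def update_belief(
    belief: Belief,
    obs: Observation | Sequence[int],
    likelihoods: Sequence[tuple[np.ndarray, float]],
    B_prev: np.ndarray,
    prev_belief: Belief,
    step: float = 0.25,
    n_iter: int = 16,
    tol: float = 1e-6,
    floor: float = LOG_FLOOR,
) -> Belief:
    """Relax the belief towards the free-energy minimum by gradient flow.

    Iterates ``upsilon <- upsilon - step * eps`` with the prediction error
    recomputed each iteration, stopping when ``max|eps| < tol`` or after
    ``n_iter`` iterations.  With the messages held fixed the free energy is
    non-increasing along the iterates and the fixed point is
    ``softmax(m)``.
    """
    if step <= 0:
        raise DomainError("step size must be positive")
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    m = log_messages(obs, likelihoods, B_prev, prev_belief, floor)
    upsilon = belief.potential.copy()
    for _ in range(n_iter):
        eps = _flog(_softmax(upsilon), floor) - m
        eps -= eps.mean()
        if np.max(np.abs(eps)) < tol:
            break
        upsilon = upsilon - step * eps
    return Belief(upsilon)


def compute_free_energy(
    belief: Belief,
    obs: Observation | Sequence[int],
    likelihoods: Sequence[tuple[np.ndarray, float]],
    B_prev: np.ndarray,
    prev_belief: Belief,
    floor: float = LOG_FLOOR,
) -> float:
    """Step-specific variational free energy ``s . (ln s - m)``.

    Bounds the negative log evidence of the observation from above; the
    bound is tight when the belief equals the exact posterior.
    """
    m = log_messages(obs, likelihoods, B_prev, prev_belief, floor)
    s = belief.probs
    return float(s @ (_flog(s, floor) - m))


def sample_action(firing_expectation: float, rng: np.random.Generator) -> int:
    """Draw a spike from a Bernoulli with the given firing expectation."""
    p = float(firing_expectation)
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise DomainError(f"firing expectation must lie in [0, 1], got {p}")
    return int(rng.random() < p)


class FreeEnergyTrace:
    """Per-neuron free-energy series with sliding-window summaries."""

    def __init__(self, values: np.ndarray):
        #: array of shape (n_steps, n_neurons)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]

    def sliding_mean(self, window: int) -> np.ndarray:
        """Trailing moving average per neuron (window clipped at the start).

        The mean of a constant series is that constant for every window
        length.
        """
        if window < 1:
            raise DomainError("window must be >= 1")
        v = self.values
        out = np.empty_like(v)
        csum = np.cumsum(v, axis=0)
        for t in range(v.shape[0]):
            lo = max(0, t - window + 1)
            total = csum[t] - (csum[lo - 1] if lo > 0 else 0.0)
            out[t] = total / (t - lo + 1)
        return out

    def ensemble_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)
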