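"""Per-neuron generative model: likelihood, precision scaling and the
history-dependent transition matrix.

Every neuron models the network it lives in as a single binary hidden state
(silent / firing) that generates one binary observation per afferent synapse
(EPSP absent / present).  Two components are defined here:

* a *precision-scaled likelihood*: each synapse carries an unnormalised 2x2
  base table ``A`` whose columns (hidden state) are raised elementwise to a
  precision ``zeta >= 0`` and renormalised.  ``zeta`` is the synaptic gain:
  at ``zeta = 0`` the synapse is uninformative (uniform likelihood), and for
  a diagonally dominant base the likelihood sharpens monotonically with
  ``zeta``;

* a *semi-Markovian transition matrix*: the two-state transition prior is a
  deterministic function of whether the neuron's own recent firing history
  contains any spike inside the window ``{tau - t_max, ..., tau - t_min}``.
  An empty window predicts firing (the network "should" burst after a long
  silence), a non-empty window predicts silence.  This single rule produces
  intrinsic burst oscillations with inter-burst onset intervals of
  ``t_max + t_min`` time steps and bursts of ``t_min`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DomainError, InvalidModelError

__all__ = [
    "LikelihoodBase",
    "GammaBelief",
    "OscillatorWindow",
    "FIRING_PREDICTED",
    "SILENCE_PREDICTED",
    "normalize_likelihood",
    "build_transition",
    "fired_from_belief",
]

#: Transition matrix selected when the recent history window holds no spike:
#: the next hidden state is "firing" with probability one (columns are the
#: conditioning previous state; both columns agree, so the prediction does
#: not depend on the previous state).
FIRING_PREDICTED = np.array([[0.0, 0.0], [1.0, 1.0]])

#: Transition matrix selected when any spike falls inside the window: the
#: next hidden state is "silent" with probability one.
SILENCE_PREDICTED = np.array([[1.0, 1.0], [0.0, 0.0]])


@dataclass(frozen=True)
class LikelihoodBase:
    """Unnormalised 2x2 likelihood weights for one synapse.

    Rows index the observation value (0 = no EPSP, 1 = EPSP), columns the
    hidden network state (0 = silent, 1 = firing).  Entries must be strictly
    positive so that arbitrary non-negative precisions yield finite
    logarithms.  Only ratios within a column matter: rescaling a column by a
    positive constant leaves the normalised likelihood unchanged.
    """

    table: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, 0.1], [0.1, 0.9]])
    )

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        if table.shape != (2, 2):
            raise InvalidModelError(
                f"likelihood base must be 2x2, got shape {table.shape}"
            )
        if not np.all(table > 0.0):
            raise InvalidModelError(
                "likelihood base entries must be strictly positive"
            )
        object.__setattr__(self, "table", table)


@dataclass(frozen=True)
class GammaBelief:
    """Gamma prior/posterior over a synaptic precision, with shape fixed at 1.

    A unit-shape gamma density ``p(zeta) = beta * exp(-beta * zeta)`` is
    parameterised by its rate alone; the expected precision is the inverse
    rate.  ``prior_rate`` is the rate of the (fixed) prior, ``posterior_rate``
    the rate of the current posterior.
    """

    prior_rate: float = 2.0
    posterior_rate: float = 2.0

    def __post_init__(self) -> None:
        if not (self.prior_rate > 0.0 and self.posterior_rate > 0.0):
            raise InvalidModelError("gamma rates must be strictly positive")

    @property
    def expected_precision(self) -> float:
        """Posterior expectation of the precision, ``1 / posterior_rate``."""
        return 1.0 / self.posterior_rate


@dataclass(frozen=True)
class OscillatorWindow:
    """History window (in time steps) that drives the transition prior.

    ``t_min`` is the refractory offset: spikes more recent than ``t_min``
    steps are invisible to the transition rule, which lets a burst extend for
    ``t_min`` consecutive steps.  ``t_max`` is the oscillator memory: once the
    last spike is more than ``t_max`` steps old the neuron again predicts
    firing.  Requires ``t_max > t_min >= 1``.
    """

    t_min: int = 5
    t_max: int = 20

    def __post_init__(self) -> None:
        if not (isinstance(self.t_min, (int, np.integer)) and self.t_min >= 1):
            raise InvalidModelError("t_min must be an integer >= 1")
        if not (
            isinstance(self.t_max, (int, np.integer)) and self.t_max > self.t_min
        ):
            raise InvalidModelError("t_max must be an integer > t_min")


def normalize_likelihood(
    base: LikelihoodBase | np.ndarray, zeta: float
) -> np.ndarray:
    """Precision-scale and column-normalise a likelihood base.

    Parameters
    ----------
    base : LikelihoodBase or array-like
        Strictly positive 2x2 table of unnormalised weights.
    zeta : float
        Non-negative precision (inverse temperature).  ``zeta = 0`` yields a
        uniform likelihood; large ``zeta`` sharpens the table towards the
        column-wise argmax.

    Returns
    -------
    ndarray
        Column-stochastic 2x2 matrix with entries
        ``base[j, h]**zeta / sum_l base[l, h]**zeta``.
    """
    if not isinstance(base, LikelihoodBase):
        base = LikelihoodBase(np.asarray(base, dtype=float))
    if not np.isfinite(zeta) or zeta < 0.0:
        raise DomainError(f"precision zeta must be finite and >= 0, got {zeta}")
    # work in log space: zeta can be large and base entries small
    logw = zeta * np.log(base.table)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=0, keepdims=True)


def build_transition(
    fired_history: Sequence[int] | np.ndarray,
    tau: int,
    window: OscillatorWindow,
) -> np.ndarray:
    """History-dependent two-state transition matrix.

    Parameters
    ----------
    fired_history : sequence of {0, 1}
        Per-step firing flags; ``fired_history[t - 1]`` is the flag for time
        step ``t`` (1-based time).  Steps before the first recorded entry are
        treated as silence.
    tau : int
        Current time step (>= 1); the window inspected is
        ``{tau - t_max, ..., tau - t_min}``.
    window : OscillatorWindow

    Returns
    -------
    ndarray
        ``FIRING_PREDICTED`` if no spike lies in the window, else
        ``SILENCE_PREDICTED``.  Both columns of either matrix are identical,
        so the implied prediction does not depend on the previous state.
    """
    if not (isinstance(tau, (int, np.integer)) and tau >= 1):
        raise DomainError(f"time index tau must be an integer >= 1, got {tau}")
    hist = np.asarray(fired_history)
    lo = max(tau - window.t_max, 1)
    hi = tau - window.t_min  # inclusive
    if hi < 1:
        return FIRING_PREDICTED.copy()
    hi = min(hi, len(hist))
    if lo > hi:
        return FIRING_PREDICTED.copy()
    if np.any(hist[lo - 1 : hi] > 0):
        return SILENCE_PREDICTED.copy()
    return FIRING_PREDICTED.copy()


def fired_from_belief(firing_expectation: float) -> int:
    """Threshold an instantaneous firing expectation into a binary flag.

    A neuron counts as having fired when its firing expectation exceeds
    chance (strictly greater than 0.5 for a two-state belief); exact ties
    count as silent.
    """
    p = float(firing_expectation)
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise DomainError(f"firing expectation must lie in [0, 1], got {p}")
    return int(p > 0.5)
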