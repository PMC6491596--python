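"""Short-term synaptic plasticity: gradient descent of free energy on
synaptic precision.

The precision ``zeta`` of each synapse has a unit-shape gamma prior with
rate ``beta`` and a gamma posterior with rate ``bbeta`` (expected precision
``1/bbeta``).  The zeta-gradient of the expected log likelihood at one time
step is

    g = s . d/dzeta ln Abar . o = sum_j ln A[:, j] . eps_o^j,
    eps_o^j = (onehot(o) - Abar[:, j]) * s_j,

an outcome prediction error weighted by the state belief: observations that
confirm the synapse's precise mapping push ``g`` positive (precision grows),
violations push it negative.  ``g`` is accumulated over a period of ``p``
time steps and the posterior rate relaxes towards the variational solution

    bbeta <- bbeta + rate * (beta - sum_tau g_tau - bbeta),

so with no evidence the posterior decays back to the prior.  The expected
precision is clamped to ``(0, zeta_max]`` in lieu of an explicit model of
synaptic homoeostasis.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import DomainError, InvalidModelError
from .generative_model import GammaBelief, LikelihoodBase, normalize_likelihood

__all__ = [
    "ZETA_MAX",
    "POSTERIOR_RATE_FLOOR",
    "PrecisionErrorAccumulator",
    "likelihood_precision_gradient",
    "update_precision",
]

logger = logging.getLogger(__name__)

#: Ceiling on the expected synaptic precision (prevents runaway excitation).
ZETA_MAX = 0.95

#: Absolute floor on the gamma posterior rate.
POSTERIOR_RATE_FLOOR = 0.05


def likelihood_precision_gradient(
    belief_probs: np.ndarray,
    obs_value: int,
    base: LikelihoodBase | np.ndarray,
    zeta: float,
) -> float:
    """Derivative of the expected log likelihood with respect to precision.

    Parameters
    ----------
    belief_probs : 2-vector
        State belief ``s`` at the time step being scored.
    obs_value : {0, 1}
        The EPSP observation carried by this synapse.
    base : LikelihoodBase or array-like
        Unnormalised likelihood table ``A``.
    zeta : float
        Current (positive) expected precision at which the normalised
        likelihood is evaluated.

    Returns
    -------
    float
        ``d/dzeta  sum_h s_h ln Abar(zeta)[o, h]``.
    """
    if not zeta > 0.0:
        raise DomainError("zeta must be strictly positive")
    if not isinstance(base, LikelihoodBase):
        base = LikelihoodBase(np.asarray(base, dtype=float))
    s = np.asarray(belief_probs, dtype=float)
    if s.shape != (2,):
        raise InvalidModelError("belief_probs must be a 2-vector")
    o = int(obs_value)
    if o not in (0, 1):
        raise DomainError("obs_value must be 0 or 1")
    abar = normalize_likelihood(base, zeta)
    log_a = np.log(base.table)
    onehot = np.zeros(2)
    onehot[o] = 1.0
    total = 0.0
    for j in (0, 1):
        eps_o = (onehot - abar[:, j]) * s[j]
        total += float(log_a[:, j] @ eps_o)
    return total


class PrecisionErrorAccumulator:
    """Running sum of per-step precision gradients over a plasticity period.

    Holds one scalar per synapse (any array shape); ``add`` accumulates,
    ``flush`` returns the period total and resets to zero.
    """

    def __init__(self, shape: tuple[int, ...] | int, period: int):
        if period < 1:
            raise DomainError("period must be >= 1")
        self.period = int(period)
        self._sum = np.zeros(shape)
        self._count = 0

    @property
    def total(self) -> np.ndarray:
        return self._sum.copy()

    @property
    def steps_accumulated(self) -> int:
        return self._count

    def add(self, gradients: np.ndarray) -> None:
        self._sum += gradients
        self._count += 1

    def boundary_reached(self) -> bool:
        return self._count >= self.period

    def flush(self) -> np.ndarray:
        out = self._sum.copy()
        self._sum[...] = 0.0
        self._count = 0
        return out


def update_precision(
    gamma: GammaBelief,
    accumulated_gradient: float,
    rate: float,
    zeta_max: float = ZETA_MAX,
    rate_floor: float = POSTERIOR_RATE_FLOOR,
) -> GammaBelief:
    """One damped update of the gamma posterior rate.

    ``posterior_rate`` moves a fraction ``rate`` towards the variational
    solution ``prior_rate - accumulated_gradient``; with zero accumulated
    gradient the posterior relaxes towards the prior.  The result is clamped
    so the expected precision stays in ``(0, zeta_max]``.
    """
    if not rate > 0.0:
        raise DomainError("learning rate must be strictly positive")
    # nextafter keeps the implied expected precision at or below zeta_max
    floor = max(rate_floor, np.nextafter(1.0 / zeta_max, np.inf))
    err = gamma.prior_rate - accumulated_gradient - gamma.posterior_rate
    new_rate = gamma.posterior_rate + rate * err
    if new_rate < floor:
        logger.warning(
            "posterior rate %.4f clamped to %.4f (precision ceiling %.2f)",
            new_rate,
            floor,
            zeta_max,
        )
        new_rate = floor
    return GammaBelief(prior_rate=gamma.prior_rate, posterior_rate=new_rate)
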