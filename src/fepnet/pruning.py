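"""Synaptic pruning by Bayesian model reduction over gamma precision priors.

A reduced model replaces a synapse's precision prior ``Gamma(1, beta)`` with
a much tighter prior ``Gamma(1, beta_tilde)`` concentrated near zero
(expected precision ``1/beta_tilde``), i.e. the synapse effectively removed.
The change in log evidence can be computed post hoc from the full model's
posterior alone:

    dF = ln E_Q[ Ptilde(zeta) / P(zeta) ]
       = ln beta_tilde - ln beta + ln bbeta - ln(bbeta - beta + beta_tilde),

valid whenever ``bbeta - beta + beta_tilde > 0`` (otherwise the gamma
expectation diverges and the reduction is not evaluable).  A synapse is
pruned when ``dF`` exceeds a threshold (default 2.5, roughly a 12-fold
evidence ratio in favour of removal); pruning is irreversible within a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Sequence

from .exceptions import DivergentEvidenceError, DomainError
from .generative_model import GammaBelief

__all__ = [
    "PRUNING_THRESHOLD",
    "ReductionDecision",
    "log_bayes_factor",
    "prune_step",
]

#: Default log Bayes factor above which a synapse is removed.
PRUNING_THRESHOLD = 2.5


@dataclass(frozen=True)
class ReductionDecision:
    """Outcome of one full-vs-reduced model comparison."""

    synapse_id: Hashable
    log_bayes_factor: float
    pruned: bool


def log_bayes_factor(
    prior_rate: float, reduced_rate: float, posterior_rate: float
) -> float:
    """Log evidence difference for removing one precision parameter.

    Parameters
    ----------
    prior_rate : float
        Rate ``beta`` of the full model's gamma prior.
    reduced_rate : float
        Rate ``beta_tilde`` of the reduced model's prior (large rate =
        precision pinned near zero).
    posterior_rate : float
        Rate ``bbeta`` of the full model's gamma posterior.

    Returns
    -------
    float
        ``ln beta_tilde - ln beta + ln bbeta - ln(bbeta - beta + beta_tilde)``,
        which is ``ln E_Q[Ptilde(zeta)/P(zeta)]`` for unit-shape gamma
        densities.  Positive values favour the reduced (synapse-free) model.
    """
    beta, bt, bb = float(prior_rate), float(reduced_rate), float(posterior_rate)
    for name, v in (("prior_rate", beta), ("reduced_rate", bt),
                    ("posterior_rate", bb)):
        if not v > 0.0:
            raise DomainError(f"{name} must be strictly positive, got {v}")
    denom = bb - beta + bt
    if denom <= 0.0:
        raise DivergentEvidenceError(
            "posterior_rate - prior_rate + reduced_rate must be positive "
            f"for the gamma expectation to converge (got {denom:.4g})"
        )
    return math.log(bt) - math.log(beta) + math.log(bb) - math.log(denom)


def prune_step(
    synapses: Sequence[tuple[Hashable, GammaBelief, bool]],
    reduced_rate: float,
    threshold: float = PRUNING_THRESHOLD,
) -> list[ReductionDecision]:
    """Evaluate Bayesian model reduction for every active synapse.

    Parameters
    ----------
    synapses : sequence of (synapse_id, GammaBelief, active)
        Inactive synapses are skipped (no decision is emitted for them).
    reduced_rate : float
        Shared rate of the reduced prior.
    threshold : float
        A synapse is pruned iff its log Bayes factor is strictly greater
        than this value; equality retains the synapse.

    Returns
    -------
    list of ReductionDecision
        One decision per active synapse, in input order.
    """
    decisions: list[ReductionDecision] = []
    for synapse_id, gamma, active in synapses:
        if not active:
            continue
        df = log_bayes_factor(gamma.prior_rate, reduced_rate,
                              gamma.posterior_rate)
        decisions.append(
            ReductionDecision(synapse_id=synapse_id, log_bayes_factor=df,
                              pruned=bool(df > threshold))
        )
    return decisions
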