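"""Exception hierarchy for fepnet.

All errors derive from :class:`FepnetError` so callers can catch the package's
failures with a single except clause; the subclasses mirror the distinct
failure modes of the model contracts.
"""


class FepnetError(Exception):
    """Base class for all fepnet errors."""


class InvalidModelError(FepnetError, ValueError):
    """A generative-model component violates its invariants
    (e.g. a non-positive likelihood entry)."""


class DomainError(FepnetError, ValueError):
    """A scalar argument lies outside its mathematical domain
    (negative precision, expectation outside [0, 1], time index < 1)."""


class ContractError(FepnetError, ValueError):
    """Mismatched shapes/lengths between coupled arguments."""


class DivergentEvidenceError(FepnetError, ArithmeticError):
    """The gamma expectation in a Bayesian model reduction does not
    converge (posterior_rate - prior_rate + reduced_rate <= 0), so the
    reduction cannot be evaluated."""


class ConfigError(FepnetError, ValueError):
    """Invalid or unknown simulation configuration."""
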