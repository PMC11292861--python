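"""Exception hierarchy for medmr.

Everything derives from :class:`MedMRError` so callers can catch the
package's failures with one clause; the concrete classes also inherit
``ValueError`` where the failure is an invalid input.
"""


class MedMRError(Exception):
    """Base class for all medmr errors."""


class FormatError(MedMRError, ValueError):
    """A summary-statistics file is malformed (e.g. a required column is absent)."""


class DomainError(MedMRError, ValueError):
    """A numeric argument is outside its valid domain (se <= 0, p outside (0, 1], ...)."""


class ContractError(MedMRError, ValueError):
    """Aligned inputs disagree in length or structure."""


class InvalidVariantError(MedMRError, ValueError):
    """A variant record violates its invariants (identical alleles, bad base, ...)."""


class EmptyIntersectionError(MedMRError, ValueError):
    """Exposure and outcome tables share no variants."""


class ConfigurationError(MedMRError, ValueError):
    """Analysis inputs are inconsistent (e.g. a variant is missing from the LD matrix)."""


class InsufficientInstrumentsError(MedMRError, ValueError):
    """Fewer instruments than the estimator requires."""


class DegenerateInstrumentError(MedMRError, ValueError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class DegenerateDesignError(MedMRError, ValueError):
    """The regression design is rank deficient (e.g. all exposure betas equal)."""
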