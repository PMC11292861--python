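"""Two-step MR mediation: effect decomposition and proportion mediated.

With a total exposure→outcome effect ``β1``, an exposure→mediator effect
``β2`` and a mediator→outcome effect ``β3`` (each from univariable MR),
the indirect effect is ``β2·β3`` and

    proportion mediated = β2·β3 / β1
    S = sqrt(β2²·se2² + β3²·se3²)
    95% CI = (β2·β3 − S)/β1  to  (β2·β3 + S)/β1

This S pairs each coefficient with its *own* standard error.  The standard
first-order delta method instead pairs each coefficient with the other
path's standard error, ``S_delta = sqrt(β2²·se3² + β3²·se2²)``; the two
coincide exactly when ``se2 = se3``.  Both variants are available
(``formula="own_se"`` — the default — or ``"delta"``); the default
keeps the own-SE pairing, matching the convention of the headline
mediation results this package is designed to reproduce; reports show both.

A mediation chain is only *consistent* (reportable) when the indirect
effect has the same sign as the total effect; e.g. the chain
(β1, β2, β3) = (0.16, −0.11, 0.17) has indirect −0.0187 against a total of
+0.16 and is rejected.

Uncertainty in β1 is not propagated: the CI formula above divides by β1
as a constant, and that is what is implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

FORMULAS = ("own_se", "delta")


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def direction_consistency(beta1: float, beta2: float, beta3: float):
    """Check that the indirect path agrees in sign with the total effect.

    Returns ``(flag, code)`` where code is one of ``"consistent"``,
    ``"opposite_sign"`` or ``"no_mediation"`` (zero indirect effect, which
    is inconsistent by convention).
    """
    indirect = beta2 * beta3
    if indirect == 0:
        return False, "no_mediation"
    if _sign(indirect) == _sign(beta1):
        return True, "consistent"
    return False, "opposite_sign"


@dataclass(frozen=True)
class MediationEstimate:
    """Effect decomposition for one exposure→mediator→outcome chain."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    indirect: float
    S: float
    proportion: float
    ci_low: float
    ci_high: float
    consistent: bool
    code: str
    formula: str

    @property
    def proportion_pct(self) -> float:
        """Proportion mediated as a percent, 1 decimal (reporting scale)."""
        return round(self.proportion * 100.0, 1)

    @property
    def ci_pct(self) -> tuple:
        return (round(self.ci_low * 100.0, 1), round(self.ci_high * 100.0, 1))


def proportion_mediated(
    beta1: float,
    beta2: float,
    beta3: float,
    se2: float,
    se3: float,
    formula: str = "own_se",
    se1: float = float("nan"),
) -> MediationEstimate:
    """Proportion of the total effect carried through the mediator.

    Parameters
    ----------
    beta1, beta2, beta3
        Total, exposure→mediator and mediator→outcome effects.
    se2, se3
        Standard errors of β2 and β3 (β1's SE enters no formula).
    formula
        ``"own_se"`` pairs each coefficient with its own SE in S;
        ``"delta"`` uses the first-order delta-method pairing.
    """
    if beta1 == 0:
        raise DomainError("beta1 = 0: proportion mediated is undefined")
    if se2 <= 0 or se3 <= 0:
        raise DomainError("se2 and se3 must be > 0")
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")

    indirect = beta2 * beta3
    if formula == "own_se":
        s = math.sqrt(beta2**2 * se2**2 + beta3**2 * se3**2)
    else:
        s = math.sqrt(beta2**2 * se3**2 + beta3**2 * se2**2)
    proportion = indirect / beta1
    lo, hi = sorted(((indirect - s) / beta1, (indirect + s) / beta1))
    consistent, code = direction_consistency(beta1, beta2, beta3)
    return MediationEstimate(
        beta1=beta1, se1=se1, beta2=beta2, se2=se2, beta3=beta3, se3=se3,
        indirect=indirect, S=s, proportion=proportion,
        ci_low=lo, ci_high=hi, consistent=consistent, code=code, formula=formula,
    )
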