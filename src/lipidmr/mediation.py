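"""Two-step MR mediation: product-of-coefficients decomposition with
delta-method uncertainty.

Given three two-sample MR estimates — a (exposure -> mediator),
b (mediator -> outcome) and c (total exposure -> outcome) — the indirect
effect is a*b, the direct effect is c - a*b, and the proportion mediated is
a*b/c.  The three estimates come from separate summary-statistic fits and
are treated as mutually independent, so the delta method gives

    se(a*b)   = sqrt(a^2 se_b^2 + b^2 se_a^2)
    se(a*b/c) = sqrt((b/c)^2 se_a^2 + (a/c)^2 se_b^2 + (a*b/c^2)^2 se_c^2)

The z test of the mediated proportion against zero (proportion /
se(proportion), two-sided normal) is the "interactive mediation test"
reported alongside the proportion; its 95% CI is symmetric about the point
estimate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimators import Z95


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with delta-method uncertainty.

    The decomposition identity ``indirect + direct == total`` holds exactly;
    ``proportion`` is on the raw scale (multiply by 100 for percent).
    """

    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float
    se_indirect: float
    direct: float
    se_direct: float
    proportion: float
    se_proportion: float
    ci_low: float
    ci_high: float
    z: float
    pval: float


def two_step_mediation(
    a: float, se_a: float, b: float, se_b: float, c: float, se_c: float,
    c_tolerance: float = 1e-10,
) -> MediationResult:
    """Decompose a total effect into mediated and direct components.

    Raises if ``|c|`` is below ``c_tolerance`` (proportion undefined) or any
    SE is non-positive.
    """
    for name, se in (("se_a", se_a), ("se_b", se_b), ("se_c", se_c)):
        if not (np.isfinite(se) and se > 0):
            raise ValueError(f"{name} must be positive and finite")
    if abs(c) < c_tolerance:
        raise ValueError("total effect ≈ 0, proportion undefined")

    indirect = a * b
    se_indirect = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    direct = c - indirect
    se_direct = float(np.sqrt(se_c**2 + se_indirect**2))

    proportion = indirect / c
    # gradient form of the delta method; robust to a or b being exactly 0
    se_proportion = float(
        np.sqrt(
            (b / c) ** 2 * se_a**2
            + (a / c) ** 2 * se_b**2
            + (indirect / c**2) ** 2 * se_c**2
        )
    )
    if se_proportion > 0:
        z = proportion / se_proportion
        pval = float(2 * sps.norm.sf(abs(z)))
    else:
        z, pval = 0.0, 1.0
    return MediationResult(
        a=a, se_a=se_a, b=b, se_b=se_b, c=c, se_c=se_c,
        indirect=float(indirect), se_indirect=se_indirect,
        direct=float(direct), se_direct=se_direct,
        proportion=float(proportion), se_proportion=se_proportion,
        ci_low=float(proportion - Z95 * se_proportion),
        ci_high=float(proportion + Z95 * se_proportion),
        z=float(z), pval=pval,
    )


def wald_p_from_or_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Reconstruct the Wald p-value implied by a printed OR and 95% CI.

    Inverts the standard reporting convention: ``se = (ln hi - ln lo) /
    (2 * 1.96)`` and ``p = two-sided normal of ln(OR)/se``.  Useful for
    checking published result tables for internal consistency; undefined
    when the lower CI bound is not strictly positive.
    """
    if not (0 < ci_low < or_value < ci_high):
        raise ValueError("require 0 < ci_low < or_value < ci_high")
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * Z95)
    z = np.log(or_value) / se
    return float(2 * sps.norm.sf(abs(z)))
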