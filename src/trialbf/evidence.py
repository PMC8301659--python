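"""Verbal evidence categories for Bayes factors.

BF01 is the ratio of marginal likelihoods null/alternative: values above 1
favor the null (no treatment effect), below 1 the alternative.  The
conventional ladder used here:

=====================  ======================
BF01                   category
=====================  ======================
<= 1/10                strong_pro_alternative
(1/10, 1/3]            moderate_pro_alternative
(1/3, 3)               ambiguous
[3, 10)                moderate_pro_null
>= 10                  strong_pro_null
=====================  ======================

Boundary values are assigned to the stronger category on the null side and
the weaker on the alternative side; boundaries are measure-zero and never
arise from floating-point pipeline output, but the convention is fixed so the
partition of (0, inf) is total.
"""

from __future__ import annotations

import math
from enum import Enum

__all__ = ["EvidenceCategory", "THRESHOLDS", "categorize"]

#: The ladder's numeric thresholds, strictly increasing.
THRESHOLDS = (1.0 / 10.0, 1.0 / 3.0, 3.0, 10.0)


class EvidenceCategory(str, Enum):
    strong_pro_alternative = "strong_pro_alternative"
    moderate_pro_alternative = "moderate_pro_alternative"
    ambiguous = "ambiguous"
    moderate_pro_null = "moderate_pro_null"
    strong_pro_null = "strong_pro_null"

    @property
    def favors_null(self) -> bool:
        return self in (self.moderate_pro_null, self.strong_pro_null)

    @property
    def favors_alternative(self) -> bool:
        return self in (self.moderate_pro_alternative, self.strong_pro_alternative)


def categorize(bf01: float) -> EvidenceCategory:
    """Map a BF01 value onto the evidence ladder.

    Raises ``ValueError`` for non-positive or non-finite input.
    """
    if not (math.isfinite(bf01) and bf01 > 0):
        raise ValueError(f"bf01 must be a positive finite number, got {bf01}")
    if bf01 <= THRESHOLDS[0]:
        return EvidenceCategory.strong_pro_alternative
    if bf01 <= THRESHOLDS[1]:
        return EvidenceCategory.moderate_pro_alternative
    if bf01 < THRESHOLDS[2]:
        return EvidenceCategory.ambiguous
    if bf01 < THRESHOLDS[3]:
        return EvidenceCategory.moderate_pro_null
    return EvidenceCategory.strong_pro_null
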