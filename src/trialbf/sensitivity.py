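"""Prior-scale sensitivity analysis for JZS Bayes factors.

A default Bayes factor depends on the Cauchy prior scale r; a robust
conclusion should not flip evidence category as r moves over the
conventional medium-to-ultrawide range.  The default grid spans
sqrt(2)/4 (narrow), sqrt(2)/2 (the default "medium"), 1 ("wide") and
sqrt(2) ("ultrawide").  An analogous check over the Beta concentration of
the contingency-table prior is provided as an optional extra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .bf_contingency import ContingencyTable2x2, mortality_bf
from .bf_t import PriorSpec, jzs_bf01
from .evidence import EvidenceCategory, categorize
from .summary_stats import TwoArmComparison

__all__ = [
    "DEFAULT_SCALE_GRID",
    "SensitivityCurve",
    "RobustnessSummary",
    "sensitivity_curve",
    "contingency_sensitivity_curve",
    "curve_frame",
    "robustness_summary",
]

DEFAULT_SCALE_GRID = (
    math.sqrt(2.0) / 4.0,
    math.sqrt(2.0) / 2.0,
    1.0,
    math.sqrt(2.0),
)


@dataclass(frozen=True)
class SensitivityCurve:
    """BF01 evaluated on an increasing grid of prior scales."""

    scales: tuple[float, ...]
    bf01_values: tuple[float, ...]
    analysis_id: str = ""

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.bf01_values):
            raise ValueError("scales and bf01_values must have equal length")
        if len(self.scales) == 0:
            raise ValueError("empty sensitivity grid")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])) is True:
            raise ValueError("scales must be strictly increasing")
        if not all(s > 0 for s in self.scales):
            raise ValueError("scales must be positive")

    @property
    def categories(self) -> tuple[EvidenceCategory, ...]:
        return tuple(categorize(v) for v in self.bf01_values)


@dataclass(frozen=True)
class RobustnessSummary:
    min_bf01: float
    max_bf01: float
    categories: frozenset
    stable: bool


def _check_grid(scales: Sequence[float]) -> tuple[float, ...]:
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("empty scale grid")
    if any(s <= 0 for s in scales):
        raise ValueError("all scales must be positive")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    return scales


def sensitivity_curve(
    cmp: TwoArmComparison,
    scales: Sequence[float] = DEFAULT_SCALE_GRID,
    analysis_id: str = "",
) -> SensitivityCurve:
    """Recompute the JZS BF01 at each Cauchy scale in ``scales``."""
    scales = _check_grid(scales)
    values = tuple(jzs_bf01(cmp, PriorSpec(scale=r)).bf01 for r in scales)
    return SensitivityCurve(scales=scales, bf01_values=values, analysis_id=analysis_id)


def contingency_sensitivity_curve(
    tab: ContingencyTable2x2,
    concentrations: Sequence[float] = (0.5, 1.0, 2.0),
    variant: str = "indep_binomial",
    analysis_id: str = "",
) -> SensitivityCurve:
    """Analogous robustness check varying the Beta prior concentration a."""
    concentrations = _check_grid(concentrations)
    values = []
    for a in concentrations:
        t = ContingencyTable2x2(
            n1=tab.n1, n2=tab.n2, y1=tab.y1, y2=tab.y2, prior_a=a
        )
        values.append(mortality_bf(t, variant=variant).bf01)
    return SensitivityCurve(
        scales=concentrations, bf01_values=tuple(values), analysis_id=analysis_id
    )


def curve_frame(curve: SensitivityCurve):
    """Tidy long-format view of a curve: (analysis_id, scale, bf01, category)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "analysis_id": curve.analysis_id,
            "scale": curve.scales,
            "bf01": curve.bf01_values,
            "category": [c.value for c in curve.categories],
        }
    )


def robustness_summary(curve: SensitivityCurve) -> RobustnessSummary:
    """Summarize a curve: BF range, categories attained, stability flag.

    ``stable`` is true iff a single evidence category is attained across the
    whole grid.
    """
    cats = frozenset(curve.categories)
    return RobustnessSummary(
        min_bf01=min(curve.bf01_values),
        max_bf01=max(curve.bf01_values),
        categories=cats,
        stable=len(cats) == 1,
    )
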