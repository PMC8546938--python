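"""Sample-size calculation for a prevalence survey.

Infinite-population formula n = ceil(DEFF * Z^2 * p(1-p) / d^2) with Z the
two-sided normal quantile of the confidence level, p the hypothesised
prevalence and d the absolute precision.  With p=0.5, 90% confidence,
d=0.05 and DEFF=1 this gives 271 per centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class SampleSizeSpec:
    hypothesized_prevalence: float = 0.5
    confidence_level: float = 0.90
    absolute_precision: float = 0.05
    design_effect: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.hypothesized_prevalence < 1:
            raise ValidationError("hypothesized_prevalence must be in (0, 1)")
        if not 0 < self.confidence_level < 1:
            raise ValidationError("confidence_level must be in (0, 1)")
        if not 0 < self.absolute_precision < 1:
            raise ValidationError("absolute_precision must be in (0, 1)")
        if self.design_effect < 1:
            raise ValidationError("design_effect must be >= 1")


def required_sample_size(spec: SampleSizeSpec) -> int:
    """Required n (per sampling unit) for the given spec."""
    z = stats.norm.ppf(0.5 + spec.confidence_level / 2)
    p = spec.hypothesized_prevalence
    d = spec.absolute_precision
    n = spec.design_effect * z * z * p * (1 - p) / (d * d)
    return math.ceil(n)
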