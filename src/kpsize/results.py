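"""Shared result container for all estimators.

Every estimator in this package (multiplier, two-source capture-recapture,
latent-class multiple systems estimation) returns an :class:`EstimateResult`:
a labelled point estimate of the hidden-population size with a 95% (by
default) uncertainty interval and enough metadata to reconstruct how it was
produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

#: ordering of method categories in reports: multipliers first, then
#: pairwise capture-recapture, then multi-list models.
CATEGORY_ORDER = {"multiplier": 0, "two-source": 1, "three-source": 2}


@dataclass(frozen=True)
class EstimateResult:
    """A labelled population-size estimate with an uncertainty interval.

    Parameters
    ----------
    method:
        Human-readable method label, e.g. ``"service multiplier"``.
    point:
        Point estimate of the population size (need not be an integer).
    ci_low, ci_high:
        Lower and upper bounds of the uncertainty interval.
    level:
        Nominal coverage of the interval, default 0.95.
    category:
        One of ``"multiplier"``, ``"two-source"``, ``"three-source"``;
        controls row ordering in reports.
    metadata:
        Free-form provenance: input counts, weighting scheme, MCMC
        settings, CI method, warnings.
    """

    method: str
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    category: str = "two-source"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.point < 0:
            raise ValueError(f"negative population estimate: {self.point}")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] does not bracket "
                f"point estimate {self.point}"
            )
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown method category: {self.category!r}")

    def as_row(self) -> dict[str, Any]:
        """Flatten to a plain dict suitable for a report table row."""
        return {
            "method": self.method,
            "estimate": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "category": self.category,
        }
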