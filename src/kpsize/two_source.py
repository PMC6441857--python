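"""Two-source (two-list) capture-recapture estimators.

Given n1 individuals captured by the first source, n2 by the second and m
by both, the Lincoln-Petersen estimator of the closed-population size is

    N_hat = n1 * n2 / m,          var = n1 n2 (n1 - m)(n2 - m) / m^3

and Chapman's small-sample bias-corrected variant, finite even at m = 0, is

    N_hat = (n1+1)(n2+1)/(m+1) - 1,
    var   = (n1+1)(n2+1)(n1-m)(n2-m) / ((m+1)^2 (m+2))

Chapman never exceeds Lincoln-Petersen and both collapse to n1 when the
two lists coincide. Validity rests on a closed population, homogeneous
capture probabilities and independent sources; positive dependence between
sources inflates m and biases both estimators downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rds_weights import RDSSample
from .results import EstimateResult

__all__ = ["TwoSourceCounts", "lincoln_petersen", "chapman", "pair_counts_from_rds"]


@dataclass(frozen=True)
class TwoSourceCounts:
    """Counts for a pair of capture sources: sizes n1, n2 and overlap m."""

    n1: int
    n2: int
    m: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.m) < 0:
            raise ValueError(f"counts must be nonnegative: {self}")
        if self.m > min(self.n1, self.n2):
            raise ValueError(
                f"overlap m={self.m} exceeds a source size (n1={self.n1}, n2={self.n2})"
            )


def _interval(nhat: float, var: float, level: float, ci_method: str, n_observed: int) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = float(np.sqrt(var))
    if ci_method == "wald":
        return max(float(n_observed), nhat - z * se), nhat + z * se
    if ci_method == "log":
        if nhat <= 0 or se == 0:
            return nhat, nhat
        c = np.exp(z * se / nhat)
        return nhat / c, nhat * c
    raise ValueError(f"unknown ci_method {ci_method!r}")


def lincoln_petersen(
    counts: TwoSourceCounts, level: float = 0.95, ci_method: str = "wald", label: str | None = None
) -> EstimateResult:
    """Lincoln-Petersen estimate N_hat = n1*n2/m with a Wald (default) interval.

    Requires m >= 1; with no overlap the estimate is undefined (infinite).
    """
    n1, n2, m = counts.n1, counts.n2, counts.m
    if m < 1:
        raise ValueError(
            "no overlap between the two sources (m = 0): Lincoln-Petersen "
            "estimate is undefined; consider the Chapman estimator"
        )
    nhat = n1 * n2 / m
    var = n1 * n2 * (n1 - m) * (n2 - m) / m**3
    n_obs = n1 + n2 - m
    lo, hi = _interval(nhat, var, level, ci_method, n_obs)
    lo = min(lo, nhat)
    meta = {"n1": n1, "n2": n2, "m": m, "variance": var, "ci_method": ci_method}
    return EstimateResult(label or "Lincoln-Petersen", float(nhat), float(lo), float(hi), level, "two-source", meta)


def chapman(
    counts: TwoSourceCounts, level: float = 0.95, ci_method: str = "wald", label: str | None = None
) -> EstimateResult:
    """Chapman bias-corrected estimate, defined for all valid counts (even m=0)."""
    n1, n2, m = counts.n1, counts.n2, counts.m
    nhat = (n1 + 1) * (n2 + 1) / (m + 1) - 1
    var = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    n_obs = n1 + n2 - m
    lo, hi = _interval(nhat, var, level, ci_method, n_obs)
    lo = min(lo, nhat)
    meta = {"n1": n1, "n2": n2, "m": m, "variance": var, "ci_method": ci_method}
    return EstimateResult(label or "Chapman", float(nhat), float(lo), float(hi), level, "two-source", meta)


def pair_counts_from_rds(sample: RDSSample, distributed: int, indicator: str) -> TwoSourceCounts:
    """Build two-source counts from an object distribution and an RDS survey.

    n1 = objects distributed, n2 = RDS sample size, m = respondents whose
    ``indicator`` column records receipt of the object. Capture-recapture
    pairs use raw (unweighted) counts; degree weighting is reserved for the
    multiplier proportions.
    """
    x = sample.indicator_values(indicator)
    m = int(np.sum(x > 0))
    n2 = len(sample)
    if m > min(distributed, n2):
        raise ValueError(
            f"data inconsistency: {m} survey respondents report the object but "
            f"only min({distributed}, {n2}) could have"
        )
    return TwoSourceCounts(n1=distributed, n2=n2, m=m)
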