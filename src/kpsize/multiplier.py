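"""Service / unique-object multiplier population-size estimator.

The multiplier method scales a known count M from one source (people who
used a service, objects distributed) by the proportion p_hat of a
representative survey reporting membership in that source:

    N_hat = M / p_hat

The survey proportion comes from :mod:`kpsize.rds_weights` (weighted or
unweighted). The default 95% interval is a delta-method interval on
log(N_hat), which keeps the lower bound positive at small p_hat; a
bootstrap interval for p_hat can be transformed instead.

An optional contamination factor in (0, 1] down-weights M when the service
register may include non-members of the hidden population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rds_weights import WeightedProportion
from .results import EstimateResult

__all__ = ["MultiplierInput", "multiplier_estimate"]


@dataclass(frozen=True)
class MultiplierInput:
    """Known first-source count plus the survey proportion reporting it."""

    count: int
    proportion: WeightedProportion

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"source count must be nonnegative, got {self.count}")


def multiplier_estimate(
    inp: MultiplierInput,
    ci_method: str = "lognormal",
    bootstrap_ci: tuple[float, float] | None = None,
    level: float = 0.95,
    contamination: float = 1.0,
    label: str = "service multiplier",
) -> EstimateResult:
    """Estimate population size as N_hat = M / p_hat with a 95% interval.

    ``ci_method``: ``"lognormal"`` (delta method on log N_hat, default),
    ``"wald"`` (symmetric delta method), or ``"bootstrap"`` (requires
    ``bootstrap_ci``, a percentile interval for p_hat, which is inverted).
    """
    if not (0.0 < contamination <= 1.0):
        raise ValueError("contamination factor must be in (0, 1]")
    M = inp.count * contamination
    p = inp.proportion.estimate
    meta = {
        "count": inp.count,
        "contamination": contamination,
        "proportion": p,
        "proportion_se": inp.proportion.se,
        "scheme": inp.proportion.scheme,
        "indicator": inp.proportion.indicator,
        "survey_n": inp.proportion.n,
        "ci_method": ci_method,
    }
    if inp.count == 0:
        warnings.warn("source count M = 0: degenerate zero estimate", stacklevel=2)
        return EstimateResult(label, 0.0, 0.0, 0.0, level, "multiplier", meta)
    if p <= 0.0:
        raise ValueError(
            "survey proportion is zero: no overlap between the source and "
            "the survey, multiplier estimate undefined"
        )
    nhat = M / p
    z = stats.norm.ppf(0.5 + level / 2.0)
    se_p = inp.proportion.se
    if ci_method == "lognormal":
        # var(log N_hat) = var(p_hat) / p_hat^2 by the delta method
        se_log = se_p / p
        lo, hi = nhat * np.exp(-z * se_log), nhat * np.exp(z * se_log)
    elif ci_method == "wald":
        se_n = M * se_p / p**2
        lo, hi = max(0.0, nhat - z * se_n), nhat + z * se_n
    elif ci_method == "bootstrap":
        if bootstrap_ci is None:
            raise ValueError("ci_method='bootstrap' requires a bootstrap_ci for p_hat")
        p_lo, p_hi = bootstrap_ci
        if p_lo <= 0:
            raise ValueError("bootstrap lower bound for p_hat must be positive")
        lo, hi = M / p_hi, M / p_lo
        lo, hi = min(lo, nhat), max(hi, nhat)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return EstimateResult(label, float(nhat), float(lo), float(hi), level, "multiplier", meta)
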