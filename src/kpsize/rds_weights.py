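"""Survey-weighted proportions from respondent-driven sampling (RDS) data.

RDS recruits participants along a social network starting from seeds, so
the raw sample over-represents high-degree individuals. The RDS-II
(Volz-Heckathorn) estimator corrects this by weighting each respondent
inversely to their reported network degree:

    p_hat = sum_i(x_i / d_i) / sum_i(1 / d_i)

The weighted proportions feed the multiplier estimators; an unweighted
scheme is available and every output records which scheme produced it.
Degrees of zero or missing are an error by default (an RDS respondent was
by construction recruited through at least one tie); median imputation is
available only behind an explicit flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RDSSample", "WeightedProportion", "rds2_proportion", "bootstrap_proportion_ci"]

REQUIRED_COLUMNS = ("id", "degree", "recruiter_id", "wave")


@dataclass(frozen=True)
class WeightedProportion:
    """A survey proportion estimate with its variance and weighting scheme."""

    estimate: float
    variance: float
    n: int
    scheme: str
    indicator: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.estimate <= 1.0):
            raise ValueError(f"proportion {self.estimate} outside [0, 1]")
        if self.variance < 0:
            raise ValueError(f"negative variance {self.variance}")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


class RDSSample:
    """An RDS survey sample: ids, degrees, recruitment links and indicators.

    Wraps a DataFrame with columns ``id, degree, recruiter_id, wave`` plus
    one binary column per indicator (service use, object receipt, ...).
    Seeds have a missing ``recruiter_id``; any non-missing recruiter must
    itself be present in the sample.
    """

    def __init__(self, data: pd.DataFrame, impute_missing_degrees: bool = False):
        missing = set(REQUIRED_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"RDS sample missing columns: {sorted(missing)}")
        if len(data) == 0:
            raise ValueError("empty RDS sample")
        df = data.copy()
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate respondent ids: {dups[:5]}")
        deg = pd.to_numeric(df["degree"], errors="coerce")
        bad = deg.isna() | (deg <= 0)
        if bad.any():
            if impute_missing_degrees:
                med = float(deg[~bad].median())
                if np.isnan(med):
                    raise ValueError("all degrees missing or nonpositive; cannot impute")
                logger.warning("imputing %d invalid degrees with sample median %.1f", int(bad.sum()), med)
                deg = deg.mask(bad, med)
            else:
                raise ValueError(
                    f"{int(bad.sum())} respondents have missing or nonpositive degree; "
                    "RDS-II weights require degree >= 1"
                )
        df["degree"] = deg.astype(float)
        rec = df["recruiter_id"].astype("string")
        rec = rec.where(~rec.isin(["", "nan", "<NA>"]), pd.NA)
        known = set(df["id"])
        unresolved = rec.dropna()[~rec.dropna().isin(known)]
        if len(unresolved):
            raise ValueError(f"recruiter ids not in sample: {unresolved.tolist()[:5]}")
        df["recruiter_id"] = rec
        self._df = df.reset_index(drop=True)

    @property
    def data(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n_seeds(self) -> int:
        return int(self._df["recruiter_id"].isna().sum())

    @property
    def max_wave(self) -> int:
        return int(self._df["wave"].max())

    def indicator_values(self, indicator: str) -> np.ndarray:
        if indicator not in self._df.columns:
            raise KeyError(
                f"indicator {indicator!r} not in sample; available: "
                f"{[c for c in self._df.columns if c not in REQUIRED_COLUMNS]}"
            )
        vals = self._df[indicator].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"indicator {indicator!r} has missing values")
        return vals

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "RDSSample":
        try:
            df = pd.read_csv(path, dtype={"id": str, "recruiter_id": str})
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"RDS file not found: {path}") from exc
        return cls(df, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)


def rds2_proportion(sample: RDSSample, indicator: str, scheme: str = "rds2") -> WeightedProportion:
    """Estimate the population proportion of ``indicator`` from an RDS sample.

    ``scheme="rds2"`` uses inverse-degree weights (RDS-II); ``"unweighted"``
    is the raw sample proportion. The variance is the Hajek linearization
    for the weighted ratio estimator, which reduces to p(1-p)/n for equal
    weights.
    """
    x = sample.indicator_values(indicator)
    n = len(sample)
    if scheme == "rds2":
        w = 1.0 / sample.data["degree"].to_numpy(dtype=float)
    elif scheme == "unweighted":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}; use 'rds2' or 'unweighted'")
    wsum = w.sum()
    p = float(np.dot(w, x) / wsum)
    var = float(np.sum((w * (x - p)) ** 2) / wsum**2)
    return WeightedProportion(estimate=p, variance=var, n=n, scheme=scheme, indicator=indicator)


def _seed_subtrees(sample: RDSSample) -> list[np.ndarray]:
    """Row indices of each seed's full observed recruitment subtree."""
    df = sample.data
    children: dict[str, list[int]] = {}
    for i, rid in enumerate(df["recruiter_id"]):
        if pd.notna(rid):
            children.setdefault(str(rid), []).append(i)
    ids = df["id"].tolist()
    trees = []
    for i in np.flatnonzero(df["recruiter_id"].isna().to_numpy()):
        stack, members = [i], []
        while stack:
            j = stack.pop()
            members.append(j)
            stack.extend(children.get(ids[j], ()))
        trees.append(np.array(members))
    return trees


def bootstrap_proportion_ci(
    sample: RDSSample,
    indicator: str,
    replicates: int = 2000,
    seed: int | None = None,
    scheme: str = "rds2",
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for an RDS proportion.

    Resamples seeds with replacement, each carrying its entire observed
    recruitment chain, so within-chain dependence is preserved. A sample
    with no recruitment links (all seeds) falls back to an individual-level
    bootstrap with a logged warning.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    trees = _seed_subtrees(sample)
    chain_level = any(len(t) > 1 for t in trees)
    if not chain_level:
        warnings.warn(
            "RDS sample has no recruitment links; falling back to "
            "individual-level bootstrap",
            stacklevel=2,
        )
    df = sample.data
    x = sample.indicator_values(indicator)
    w = 1.0 / df["degree"].to_numpy(dtype=float) if scheme == "rds2" else np.ones(len(df))
    stats = np.empty(replicates)
    if chain_level:
        k = len(trees)
        for b in range(replicates):
            picks = rng.integers(0, k, size=k)
            idx = np.concatenate([trees[i] for i in picks])
            stats[b] = np.dot(w[idx], x[idx]) / w[idx].sum()
    else:
        n = len(df)
        for b in range(replicates):
            idx = rng.integers(0, n, size=n)
            stats[b] = np.dot(w[idx], x[idx]) / w[idx].sum()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
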