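"""Data model and I/O for capture histories and capture-profile tables.

A *capture source* (a unique-object distribution round, a survey, a service
register) either captures an individual or does not; an individual's
*capture history* is the binary vector over the study's ordered sources.
Only nonzero histories are observable, so a study with J sources yields an
aggregate table of 2^J - 1 profile counts — the sufficient statistic for
every capture-recapture estimator in this package.

Profiles are encoded as fixed-order bitstrings over the declared sources
(first source = leftmost character); source order is declared once per
study and never inferred, preventing silent column misalignment between
capture rounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CaptureRecord",
    "AggregateCaptureTable",
    "DistributionTally",
    "aggregate_histories",
    "marginal_count",
    "tally_rate",
    "read_capture_histories",
    "write_capture_histories",
]


def _check_sources(sources: Sequence[str]) -> tuple[str, ...]:
    sources = tuple(str(s) for s in sources)
    if not sources:
        raise ValueError("at least one capture source is required")
    if any(not s for s in sources):
        raise ValueError("source labels must be nonempty")
    if len(set(sources)) != len(sources):
        raise ValueError(f"duplicate source labels: {sources}")
    return sources


def all_profiles(n_sources: int) -> list[str]:
    """All 2^J - 1 observable (nonzero) profile bitstrings, in binary order."""
    return [
        "".join(map(str, bits))
        for bits in itertools.product((0, 1), repeat=n_sources)
        if any(bits)
    ]


@dataclass(frozen=True)
class CaptureRecord:
    """One individual's binary membership across the study's capture sources."""

    individual_id: str
    indicators: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(x not in (0, 1) for x in self.indicators):
            raise ValueError(
                f"indicators must be 0/1, got {self.indicators} "
                f"for id {self.individual_id!r}"
            )

    @property
    def profile(self) -> str:
        return "".join(map(str, self.indicators))


@dataclass(frozen=True)
class AggregateCaptureTable:
    """Counts of the 2^J - 1 observable capture profiles for J ordered sources."""

    sources: tuple[str, ...]
    counts: dict[str, int] = field(compare=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", _check_sources(self.sources))
        expected = all_profiles(len(self.sources))
        counts = {p: int(self.counts.get(p, 0)) for p in expected}
        unknown = set(self.counts) - set(expected)
        if unknown:
            raise ValueError(f"invalid profiles for {len(self.sources)} sources: {sorted(unknown)}")
        if any(c < 0 for c in counts.values()):
            raise ValueError("profile counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_observed(self) -> int:
        """Total number of observed (captured-at-least-once) individuals."""
        return sum(self.counts.values())

    def marginal(self, source: str) -> int:
        return marginal_count(self, source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"profile": list(self.counts), "count": list(self.counts.values())}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sources: Sequence[str]) -> "AggregateCaptureTable":
        try:
            df = pd.read_csv(path, dtype={"profile": str})
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"aggregate-table file not found: {path}") from exc
        if not {"profile", "count"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'profile,count', got {list(df.columns)}")
        counts = dict(zip(df["profile"], df["count"].astype(int)))
        return cls(tuple(sources), counts)


@dataclass(frozen=True)
class DistributionTally:
    """Aggregate accounting of one unique-object distribution round.

    Tracks how many individuals the distributors approached (``contacted``),
    how many agreed to participate, how many received the object during this
    round (``newly_received``) and how many already carried it from an
    earlier encounter (``already_received``).
    """

    contacted: int
    agreed: int
    newly_received: int
    already_received: int

    def __post_init__(self) -> None:
        vals = (self.contacted, self.agreed, self.newly_received, self.already_received)
        if any(v < 0 for v in vals):
            raise ValueError(f"tally counts must be nonnegative: {vals}")
        if self.agreed > self.contacted:
            raise ValueError("agreed cannot exceed contacted")
        if self.newly_received + self.already_received > self.contacted:
            raise ValueError("received counts cannot exceed contacted")


def aggregate_histories(records: Iterable[CaptureRecord], sources: Sequence[str]) -> AggregateCaptureTable:
    """Tally individual capture histories into an aggregate profile table.

    Raises on duplicate ids (inputs must be deduplicated upstream) and on
    all-zero histories, which are unobservable by construction.
    """
    sources = _check_sources(sources)
    records = list(records)
    if not records:
        raise ValueError("no observed individuals: cannot build a capture table")
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for rec in records:
        if len(rec.indicators) != len(sources):
            raise ValueError(
                f"record {rec.individual_id!r} has {len(rec.indicators)} indicators "
                f"for {len(sources)} sources"
            )
        if rec.individual_id in seen:
            raise ValueError(f"duplicate individual_id: {rec.individual_id!r}")
        seen.add(rec.individual_id)
        if not any(rec.indicators):
            raise ValueError(
                f"record {rec.individual_id!r} has an all-zero capture history "
                "(unobservable)"
            )
        counts[rec.profile] = counts.get(rec.profile, 0) + 1
    return AggregateCaptureTable(sources, counts)


def marginal_count(table: AggregateCaptureTable, source: str) -> int:
    """Number of individuals captured by ``source`` (any overlap included)."""
    if source not in table.sources:
        raise KeyError(f"unknown source {source!r}; table has {table.sources}")
    j = table.sources.index(source)
    return sum(c for p, c in table.counts.items() if p[j] == "1")


def tally_rate(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``decimals``.

    Matches the reporting style of field tallies such as acceptance and
    already-received rates.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if numerator < 0:
        raise ValueError(f"numerator must be nonnegative, got {numerator}")
    return round(100.0 * numerator / denominator, decimals)


def write_capture_histories(records: Iterable[CaptureRecord], sources: Sequence[str], path: str | Path) -> None:
    """Write individual capture histories as CSV: ``id,<source1>,<source2>,...``."""
    sources = _check_sources(sources)
    rows = [{"id": r.individual_id, **dict(zip(sources, r.indicators))} for r in records]
    pd.DataFrame(rows, columns=["id", *sources]).to_csv(path, index=False)


def read_capture_histories(path: str | Path) -> tuple[list[CaptureRecord], tuple[str, ...]]:
    """Read a capture-history CSV; returns (records, source order from header)."""
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"capture-history file not found: {path}") from exc
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    sources = _check_sources(df.columns[1:])
    ids = df["id"].astype(str).tolist()
    indicator_rows = df[list(sources)].astype(int).to_numpy()
    records = [
        CaptureRecord(ident, tuple(int(x) for x in row))
        for ident, row in zip(ids, indicator_rows)
    ]
    return records, sources
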