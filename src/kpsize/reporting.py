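"""Assemble estimates into a study report.

Collects the point estimates and 95% intervals from all methods into one
table, adds the proportion-of-reference-population column (estimate as a
percentage of, e.g., the census count of females aged 15-64 in the study
area), flags implausible rows exceeding 100% of the reference population
(a symptom of closure violations or contaminated source counts), and
renders deterministic CSV / plain-text output.

No automated "final estimate" selection is performed: choosing among
divergent methods is an analyst judgment, so the report only supports a
manually designated final row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .results import CATEGORY_ORDER, EstimateResult

logger = logging.getLogger(__name__)

__all__ = ["PopulationContext", "StudyReport", "proportion_of_population", "build_report"]


@dataclass(frozen=True)
class PopulationContext:
    """Reference denominator for the proportion column."""

    reference_count: int
    reference_year: int | None = None
    area: str = ""

    def __post_init__(self) -> None:
        if self.reference_count <= 0:
            raise ValueError(f"reference_count must be positive, got {self.reference_count}")


def proportion_of_population(estimate: EstimateResult, context: PopulationContext, decimals: int = 2) -> float:
    """Point estimate as a percentage of the reference population.

    Values over 100% are permitted (and flagged downstream): an estimated
    hidden population exceeding the whole reference population is a clear
    plausibility failure, not an arithmetic one.
    """
    pct = round(100.0 * estimate.point / context.reference_count, decimals)
    if pct > 100.0:
        logger.warning(
            "estimate '%s' (%s) is %.2f%% of the reference population: "
            "likely closure violation or contaminated source count",
            estimate.method, estimate.point, pct,
        )
    return pct


@dataclass
class StudyReport:
    """One study area's estimate table plus run provenance."""

    area: str
    context: PopulationContext
    estimates: list[EstimateResult]
    final_method: str | None = None
    fingerprint: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates:
            pct = proportion_of_population(est, self.context)
            rows.append(
                {
                    **est.as_row(),
                    "pct_of_reference": pct,
                    "plausibility_flag": "exceeds reference population" if pct > 100 else "",
                    "final": est.method == self.final_method,
                }
            )
        df = pd.DataFrame(rows)
        df = df.sort_values(
            by=["category", "method"],
            key=lambda s: s.map(CATEGORY_ORDER) if s.name == "category" else s,
            kind="stable",
        ).reset_index(drop=True)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def render_text(self) -> str:
        df = self.to_frame()
        header = f"Population size estimates — {self.area} (reference population {self.context.reference_count:,})"
        lines = [header, "=" * len(header)]
        for row in df.itertuples(index=False):
            mark = " *" if row.final else ""
            flag = f"  [{row.plausibility_flag}]" if row.plausibility_flag else ""
            lines.append(
                f"{row.method:<38s} {row.estimate:>10.1f}  "
                f"(95% CI {row.ci_low:.1f}-{row.ci_high:.1f})  "
                f"{row.pct_of_reference:>7.2f}%{flag}{mark}"
            )
        if self.final_method:
            lines.append("* designated final estimate")
        return "\n".join(lines) + "\n"

    def write(self, output_dir: str | Path) -> dict[str, Path]:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "csv": out / "report.csv",
            "text": out / "report.txt",
            "provenance": out / "report_provenance.json",
        }
        self.to_csv(paths["csv"])
        paths["text"].write_text(self.render_text())
        prov = {
            "area": self.area,
            "reference_count": self.context.reference_count,
            "reference_year": self.context.reference_year,
            "final_method": self.final_method,
            "fingerprint": self.fingerprint,
            "estimates": [
                {**e.as_row(), "metadata": _jsonable(e.metadata)} for e in self.estimates
            ],
        }
        paths["provenance"].write_text(json.dumps(prov, indent=2, sort_keys=True))
        return paths


def build_report(
    estimates: list[EstimateResult],
    context: PopulationContext,
    area: str = "",
    final_method: str | None = None,
    fingerprint: dict | None = None,
) -> StudyReport:
    """Build a deterministic multi-method report (multipliers first, then
    pairwise capture-recapture, then multi-list models)."""
    if not estimates:
        raise ValueError("need at least one estimate to build a report")
    if final_method is not None and final_method not in {e.method for e in estimates}:
        raise ValueError(f"final_method {final_method!r} not among the estimates")
    return StudyReport(
        area=area or context.area,
        context=context,
        estimates=list(estimates),
        final_method=final_method,
        fingerprint=fingerprint or {},
    )


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
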