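"""Cohort-level failure-rate summaries and report rendering.

Aggregates reviewed failure records into a per-organ table of flagged
failures, censored counts, the failure-mode breakdown, true-failure
counts and rates, plus the pooled rate across organs and the censored
fraction of all initial flags.  Rates are rendered as percentages at one
decimal place with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from ._exceptions import ConsistencyError, RoutingError
from .review import FAILURE_CATEGORIES, FailureRecord

__all__ = [
    "OrganSummary",
    "CohortSummary",
    "summarize_cohort",
    "format_report",
    "plot_data",
    "round_percent",
]

#: Table row order of the rendered report.
REPORT_ROWS = (
    "Failures",
    "Censored (sub-optimal manual contour)",
    "Setup position",
    "Anatomical",
    "Image artefacts",
    "Unknown",
    "True failures",
    "True failure rate",
)

_CATEGORY_ROW = {
    "setup": "Setup position",
    "anatomy": "Anatomical",
    "artefacts": "Image artefacts",
    "unknown": "Unknown",
}


def round_percent(fraction: float, ndigits: int = 1) -> float:
    """Render a fraction as a percentage, half-up at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class OrganSummary:
    organ_name: str
    n_evaluated: int
    n_flagged: int
    n_censored: int
    category_counts: Mapping[str, int]
    n_true_failures: int
    true_failure_rate: float

    def __post_init__(self):
        if self.n_true_failures != self.n_flagged - self.n_censored:
            raise ConsistencyError("true failures must equal flagged - censored")
        if sum(self.category_counts.values()) != self.n_true_failures:
            raise ConsistencyError("category counts must sum to true failures")


@dataclass(frozen=True)
class CohortSummary:
    organs: tuple[OrganSummary, ...]
    total_true_failures: int
    total_evaluated: int
    overall_rate: float
    censored_fraction_of_flagged: Optional[float]  # None when nothing flagged


def summarize_cohort(
    records: Iterable[FailureRecord],
    n_evaluated_per_organ: Union[int, Mapping[str, int]],
    organs: Optional[Iterable[str]] = None,
) -> CohortSummary:
    """Aggregate reviewed records into per-organ and pooled failure rates.

    ``n_evaluated_per_organ`` is the full cohort size per organ (censored
    records stay in this denominator); pass a mapping for unequal organ
    cohorts.  Record order never matters.
    """
    records = list(records)
    organ_names = sorted(
        set(r.organ_name for r in records) | set(organs or [])
    )
    if isinstance(n_evaluated_per_organ, Mapping):
        n_eval = {o: int(n_evaluated_per_organ[o]) for o in organ_names}
        unknown = set(r.organ_name for r in records) - set(n_evaluated_per_organ)
        if unknown:
            raise RoutingError(f"records reference unknown organ(s): {sorted(unknown)}")
    else:
        n_eval = {o: int(n_evaluated_per_organ) for o in organ_names}

    summaries = []
    for organ in organ_names:
        rs = [r for r in records if r.organ_name == organ]
        n_censored = sum(r.status == "censored" for r in rs)
        n_true = sum(r.status == "true_failure" for r in rs)
        n_flagged = n_censored + n_true
        if n_eval[organ] < n_flagged:
            raise ConsistencyError(
                f"{organ!r}: n_evaluated {n_eval[organ]} < flagged {n_flagged}"
            )
        cats = {c: 0 for c in FAILURE_CATEGORIES}
        for r in rs:
            if r.status == "true_failure":
                cats[r.category] += 1
        summaries.append(
            OrganSummary(
                organ_name=organ,
                n_evaluated=n_eval[organ],
                n_flagged=n_flagged,
                n_censored=n_censored,
                category_counts=cats,
                n_true_failures=n_true,
                true_failure_rate=n_true / n_eval[organ] if n_eval[organ] else 0.0,
            )
        )
    total_true = sum(s.n_true_failures for s in summaries)
    total_eval = sum(s.n_evaluated for s in summaries)
    total_flagged = sum(s.n_flagged for s in summaries)
    total_censored = sum(s.n_censored for s in summaries)
    return CohortSummary(
        organs=tuple(summaries),
        total_true_failures=total_true,
        total_evaluated=total_eval,
        overall_rate=total_true / total_eval if total_eval else 0.0,
        censored_fraction_of_flagged=(
            total_censored / total_flagged if total_flagged else None
        ),
    )


def format_report(summary: CohortSummary) -> pd.DataFrame:
    """Render the cohort summary as the standard 8-row report table.

    Rows: flagged failures, censored, the four failure modes, true
    failures, and the true-failure rate as a percent string at 1 d.p.
    Columns: one per organ.  An empty summary yields a header-only frame.
    """
    data: dict[str, list] = {}
    for s in summary.organs:
        data[s.organ_name] = [
            s.n_flagged,
            s.n_censored,
            s.category_counts["setup"],
            s.category_counts["anatomy"],
            s.category_counts["artefacts"],
            s.category_counts["unknown"],
            s.n_true_failures,
            f"{round_percent(s.true_failure_rate):.1f}%",
        ]
    index = list(REPORT_ROWS) if data else []
    return pd.DataFrame(data, index=index)


def summary_from_report(df: pd.DataFrame, n_evaluated_per_organ) -> CohortSummary:
    """Rebuild a CohortSummary from a report table (round-trip check)."""
    organs = []
    for organ in df.columns:
        col = df[organ]
        n_eval = (
            n_evaluated_per_organ[organ]
            if isinstance(n_evaluated_per_organ, Mapping)
            else n_evaluated_per_organ
        )
        cats = {
            "setup": int(col["Setup position"]),
            "anatomy": int(col["Anatomical"]),
            "artefacts": int(col["Image artefacts"]),
            "unknown": int(col["Unknown"]),
        }
        organs.append(
            OrganSummary(
                organ_name=organ,
                n_evaluated=int(n_eval),
                n_flagged=int(col["Failures"]),
                n_censored=int(col["Censored (sub-optimal manual contour)"]),
                category_counts=cats,
                n_true_failures=int(col["True failures"]),
                true_failure_rate=int(col["True failures"]) / int(n_eval),
            )
        )
    total_true = sum(s.n_true_failures for s in organs)
    total_eval = sum(s.n_evaluated for s in organs)
    total_flagged = sum(s.n_flagged for s in organs)
    total_censored = sum(s.n_censored for s in organs)
    return CohortSummary(
        organs=tuple(organs),
        total_true_failures=total_true,
        total_evaluated=total_eval,
        overall_rate=total_true / total_eval if total_eval else 0.0,
        censored_fraction_of_flagged=(
            total_censored / total_flagged if total_flagged else None
        ),
    )


def plot_data(records: Iterable[FailureRecord]) -> pd.DataFrame:
    """Per-patient DSC series with the failure line, for control charts.

    One row per record: (organ, patient index, patient_id, dsc, limit,
    status) — the data behind a per-organ scatter with the gross-failure
    limit drawn as a horizontal line.
    """
    rows = []
    by_organ: dict[str, int] = {}
    for r in records:
        idx = by_organ.get(r.organ_name, 0)
        by_organ[r.organ_name] = idx + 1
        rows.append(
            {
                "organ": r.organ_name,
                "patient_index": idx,
                "patient_id": r.patient_id,
                "dsc": r.flag.metric_result.dsc,
                "dsc_lower_limit": r.flag.limits_used.dsc_lower_limit,
                "status": r.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["organ", "patient_index", "patient_id", "dsc", "dsc_lower_limit", "status"],
    )


def summary_to_json(summary: CohortSummary) -> dict:
    return {
        "organs": [
            {
                "organ": s.organ_name,
                "n_evaluated": s.n_evaluated,
                "n_flagged": s.n_flagged,
                "n_censored": s.n_censored,
                "categories": dict(s.category_counts),
                "n_true_failures": s.n_true_failures,
                "true_failure_rate_pct": round_percent(s.true_failure_rate),
            }
            for s in summary.organs
        ],
        "total_true_failures": summary.total_true_failures,
        "total_evaluated": summary.total_evaluated,
        "overall_rate_pct": round_percent(summary.overall_rate),
        "censored_fraction_of_flagged_pct": (
            None
            if summary.censored_fraction_of_flagged is None
            else round_percent(summary.censored_fraction_of_flagged)
        ),
    }
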