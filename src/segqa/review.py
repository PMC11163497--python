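"""Expert-review bookkeeping for flagged gross failures.

Flagged contours are inspected by a human expert; the review verdict
either censors the flag (the *manual* gold contour, not the AI contour,
was suboptimal) or assigns one of four failure modes: non-standard setup
position, non-standard anatomy (e.g. post-surgery), CT image artefacts
(e.g. dental fillings), or unknown.  This module only enforces the
bookkeeping — review itself is never automated.

Censoring removes a record from the true-failure numerator but not from
the cohort denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from ._exceptions import AnnotationConflictError, IncompleteReviewError
from .model import GrossFailureFlag

__all__ = [
    "VERDICTS",
    "FAILURE_CATEGORIES",
    "ReviewAnnotation",
    "FailureRecord",
    "apply_review",
    "read_annotations_csv",
    "write_annotations_csv",
]

#: Failure-mode categories assignable to a true failure.
FAILURE_CATEGORIES = ("setup", "anatomy", "artefacts", "unknown")
#: Closed verdict vocabulary: censoring plus the four failure modes.
VERDICTS = ("censored_suboptimal_manual",) + FAILURE_CATEGORIES

STATUSES = ("not_failed", "censored", "true_failure")


@dataclass(frozen=True)
class ReviewAnnotation:
    patient_id: str
    organ_name: str
    verdict: str
    note: str = ""

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(
                f"verdict {self.verdict!r} not in the closed set {VERDICTS}"
            )


@dataclass(frozen=True)
class FailureRecord:
    """A flag after review: not_failed, censored, or a categorised failure."""

    flag: GrossFailureFlag
    status: str
    category: Optional[str] = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.category is not None) != (self.status == "true_failure"):
            raise ValueError("category present iff status is 'true_failure'")

    @property
    def patient_id(self) -> str:
        return self.flag.metric_result.patient_id

    @property
    def organ_name(self) -> str:
        return self.flag.metric_result.organ_name


def apply_review(
    flags: Iterable[GrossFailureFlag],
    annotations: Iterable[ReviewAnnotation],
) -> list[FailureRecord]:
    """Join DSC-failure flags with expert annotations.

    Every DSC-failed flag needs exactly one annotation keyed on
    (patient_id, organ_name); non-failed results need none (extras raise a
    warning).  Pure function: identical inputs yield identical records.
    """
    ann_by_key: dict[tuple[str, str], ReviewAnnotation] = {}
    for a in annotations:
        key = (a.patient_id, a.organ_name)
        if key in ann_by_key:
            raise AnnotationConflictError(
                f"duplicate annotation for patient {a.patient_id!r}, "
                f"organ {a.organ_name!r}"
            )
        ann_by_key[key] = a

    records: list[FailureRecord] = []
    used: set[tuple[str, str]] = set()
    for flag in flags:
        key = (flag.metric_result.patient_id, flag.metric_result.organ_name)
        if not flag.dsc_failed:
            records.append(FailureRecord(flag=flag, status="not_failed"))
            continue
        ann = ann_by_key.get(key)
        if ann is None:
            raise IncompleteReviewError(
                f"flagged failure without annotation: patient {key[0]!r}, "
                f"organ {key[1]!r}"
            )
        used.add(key)
        if ann.verdict == "censored_suboptimal_manual":
            records.append(FailureRecord(flag=flag, status="censored"))
        else:
            records.append(
                FailureRecord(flag=flag, status="true_failure", category=ann.verdict)
            )
    orphans = set(ann_by_key) - used
    if orphans:
        warnings.warn(
            f"{len(orphans)} annotation(s) match no flagged failure: "
            f"{sorted(orphans)[:5]}",
            stacklevel=2,
        )
    return records


def read_annotations_csv(path) -> list[ReviewAnnotation]:
    df = pd.read_csv(path, dtype=str).fillna("")
    return [
        ReviewAnnotation(
            patient_id=r["patient_id"],
            organ_name=r["organ"],
            verdict=r["verdict"],
            note=r.get("note", ""),
        )
        for _, r in df.iterrows()
    ]


def write_annotations_csv(annotations: Iterable[ReviewAnnotation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "organ": a.organ_name,
                "verdict": a.verdict,
                "note": a.note,
            }
            for a in annotations
        ],
        columns=["patient_id", "organ", "verdict", "note"],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
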