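"""Review bookkeeping and cohort failure-rate reporting."""

import numpy as np
import pytest

from segqa.metrics import MetricResult
from segqa.model import compute_reference_limits, flag_gross_failures
from segqa.report import (
    format_report,
    plot_data,
    round_percent,
    summarize_cohort,
    summary_from_report,
    summary_to_json,
)
from segqa.review import FailureRecord, ReviewAnnotation, apply_review
from segqa._exceptions import (
    AnnotationConflictError,
    ConsistencyError,
    IncompleteReviewError,
)

LIMITS = {
    o: compute_reference_limits(o, [m - s, m, m + s])
    for o, (m, s) in {
        "brainstem": (0.81, 0.06),
        "mandible": (0.91, 0.02),
        "parotid_l": (0.76, 0.06),
        "parotid_r": (0.74, 0.08),
    }.items()
}


def make_flags(organ, n_failed, n_passed):
    """n_failed sub-limit and n_passed at-mean results, flagged."""
    lim = LIMITS[organ]
    results = [
        MetricResult(f"{organ}-fail-{i}", organ, 0.30, None, 0, 0, 0)
        for i in range(n_failed)
    ] + [
        MetricResult(f"{organ}-ok-{i}", organ, lim.dsc_mean, None, 0, 0, 0)
        for i in range(n_passed)
    ]
    return flag_gross_failures(results, lim)


def ann(organ, pid, verdict):
    return ReviewAnnotation(patient_id=pid, organ_name=organ, verdict=verdict)


#: The audited 500-patient cohort's review outcome per organ:
#: (flagged, censored, {category: count}).
COHORT_REVIEW = {
    "brainstem": (4, 2, {"setup": 2}),
    "mandible": (20, 9, {"anatomy": 8, "artefacts": 3}),
    "parotid_l": (13, 6, {"anatomy": 5, "unknown": 2}),
    "parotid_r": (7, 3, {"setup": 1, "anatomy": 2, "artefacts": 1}),
}


def cohort_records():
    records = []
    for organ, (n_flagged, n_censored, cats) in COHORT_REVIEW.items():
        flags = make_flags(organ, n_flagged, 0)
        annotations = []
        i = 0
        for _ in range(n_censored):
            annotations.append(ann(organ, f"{organ}-fail-{i}", "censored_suboptimal_manual"))
            i += 1
        for cat, count in cats.items():
            for _ in range(count):
                annotations.append(ann(organ, f"{organ}-fail-{i}", cat))
                i += 1
        records.extend(apply_review(flags, annotations))
    return records


class TestApplyReview:
    def test_censored_and_true_failures_split(self):
        flags = make_flags("brainstem", 4, 16)
        annotations = [
            ann("brainstem", "brainstem-fail-0", "censored_suboptimal_manual"),
            ann("brainstem", "brainstem-fail-1", "censored_suboptimal_manual"),
            ann("brainstem", "brainstem-fail-2", "setup"),
            ann("brainstem", "brainstem-fail-3", "setup"),
        ]
        records = apply_review(flags, annotations)
        statuses = [r.status for r in records]
        assert statuses.count("censored") == 2
        assert statuses.count("true_failure") == 2
        assert statuses.count("not_failed") == 16
        assert all(r.category == "setup" for r in records if r.status == "true_failure")

    def test_empty_inputs(self):
        assert apply_review([], []) == []

    def test_missing_annotation_raises(self):
        flags = make_flags("brainstem", 3, 0)
        annotations = [
            ann("brainstem", "brainstem-fail-0", "setup"),
            ann("brainstem", "brainstem-fail-1", "setup"),
        ]
        with pytest.raises(IncompleteReviewError):
            apply_review(flags, annotations)

    def test_duplicate_annotation_raises(self):
        flags = make_flags("brainstem", 1, 0)
        dup = [ann("brainstem", "brainstem-fail-0", "setup")] * 2
        with pytest.raises(AnnotationConflictError):
            apply_review(flags, dup)

    def test_orphan_annotation_warns(self):
        flags = make_flags("brainstem", 0, 2)
        with pytest.warns(UserWarning, match="match no flagged"):
            apply_review(flags, [ann("brainstem", "nobody", "setup")])

    def test_invalid_verdict_rejected(self):
        with pytest.raises(ValueError):
            ReviewAnnotation("p", "o", "typo_verdict")

    def test_conservation_and_purity(self):
        flags = make_flags("mandible", 5, 7)
        annotations = [
            ann("mandible", f"mandible-fail-{i}", v)
            for i, v in enumerate(
                ["censored_suboptimal_manual", "anatomy", "anatomy", "artefacts", "unknown"]
            )
        ]
        r1 = apply_review(flags, annotations)
        r2 = apply_review(flags, annotations)
        assert len(r1) == 12
        counts = {s: sum(r.status == s for r in r1) for s in ("not_failed", "censored", "true_failure")}
        assert sum(counts.values()) == 12
        assert counts["censored"] + counts["true_failure"] == 5
        assert [(r.status, r.category) for r in r1] == [(r.status, r.category) for r in r2]


class TestSummarize:
    def test_cohort_counts_and_rates(self):
        summary = summarize_cohort(cohort_records(), 500)
        by = {s.organ_name: s for s in summary.organs}
        assert [by[o].n_true_failures for o in ("brainstem", "mandible", "parotid_l", "parotid_r")] == [2, 11, 7, 4]
        assert [round_percent(by[o].true_failure_rate) for o in ("brainstem", "mandible", "parotid_l", "parotid_r")] == [0.4, 2.2, 1.4, 0.8]
        assert summary.total_true_failures == 24
        assert round_percent(summary.overall_rate) == 1.2
        assert round_percent(summary.censored_fraction_of_flagged) == 45.5

    def test_permutation_invariance(self, rng):
        records = cohort_records()
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = summarize_cohort(records, 500)
        b = summarize_cohort(shuffled, 500)
        assert summary_to_json(a) == summary_to_json(b)

    def test_empty_cohort(self):
        summary = summarize_cohort([], 500)
        assert summary.total_true_failures == 0
        assert summary.censored_fraction_of_flagged is None
        assert format_report(summary).empty

    def test_zero_flagged_rates(self):
        records = [FailureRecord(flag=f, status="not_failed") for f in make_flags("brainstem", 0, 5)]
        summary = summarize_cohort(records, 500)
        [org] = summary.organs
        assert org.true_failure_rate == 0.0
        assert summary.censored_fraction_of_flagged is None

    def test_n_evaluated_consistency(self):
        with pytest.raises(ConsistencyError):
            summarize_cohort(cohort_records(), 10)


class TestFormatReport:
    def test_table_layout_and_rate_rendering(self):
        df = format_report(summarize_cohort(cohort_records(), 500))
        assert list(df.index) == [
            "Failures",
            "Censored (sub-optimal manual contour)",
            "Setup position",
            "Anatomical",
            "Image artefacts",
            "Unknown",
            "True failures",
            "True failure rate",
        ]
        assert df.shape == (8, 4)
        assert df.loc["True failure rate", "brainstem"] == "0.4%"
        assert df.loc["Failures", "mandible"] == 20

    def test_report_roundtrip(self):
        summary = summarize_cohort(cohort_records(), 500)
        df = format_report(summary)
        back = summary_from_report(df, 500)
        assert summary_to_json(back) == summary_to_json(summary)

    @pytest.mark.parametrize(
        "fraction, expected",
        [(0.004, 0.4), (24 / 2000, 1.2), (20 / 44, 45.5), (0.0215, 2.2), (0.125, 12.5)],
    )
    def test_half_up_percent_rounding(self, fraction, expected):
        assert round_percent(fraction) == expected

    def test_plot_data_columns(self):
        df = plot_data(cohort_records())
        assert list(df.columns) == [
            "organ", "patient_index", "patient_id", "dsc", "dsc_lower_limit", "status",
        ]
        assert (df.groupby("organ")["patient_index"].max() + 1).tolist() == [4, 20, 13, 7]
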