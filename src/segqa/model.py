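"""Three-sigma reference limits for contour QA, statsmodels-style.

The reference cohort of DSC (and optionally HD95) values per organ plays
the role of the data a model is fitted to.  :class:`ContourQAModel.fit`
estimates, per organ, the arithmetic mean and sample standard deviation
(n−1 denominator) and derives one-sided control limits:

* DSC lower limit ``mean − 3·SD`` (clamped at 0) — a gross failure is a
  DSC strictly below this limit, so with ~normal reference behaviour
  ≈99.7% of non-failing results stay above it (one-sided tail ≈0.135%).
* HD95 upper limit ``mean + 3·SD`` — flagged when strictly above.

The returned :class:`ContourQAResults` carries the estimates, their
standard errors, a ``summary()`` table, and the flagging/audit methods
that apply the limits to a test cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import DomainError, InsufficientDataError, RoutingError
from .metrics import MetricResult

__all__ = [
    "ReferenceLimits",
    "GrossFailureFlag",
    "compute_reference_limits",
    "flag_gross_failures",
    "ContourQAModel",
    "ContourQAResults",
]

N_SIGMA = 3.0


@dataclass(frozen=True)
class ReferenceLimits:
    """Per-organ reference statistics and control limits."""

    organ_name: str
    dsc_mean: float
    dsc_sd: float
    dsc_lower_limit: float
    n_reference: int
    hd_mean: Optional[float] = None
    hd_sd: Optional[float] = None
    hd_upper_limit: Optional[float] = None

    def __post_init__(self):
        if self.n_reference < 2:
            raise InsufficientDataError(
                f"{self.organ_name!r}: reference limits need >= 2 values"
            )
        if self.dsc_sd > 0 and not self.dsc_lower_limit < self.dsc_mean:
            raise ValueError("dsc_lower_limit must lie below dsc_mean")


@dataclass(frozen=True)
class GrossFailureFlag:
    """A metric result judged against reference limits.

    ``hd_failed`` is ``None`` when HD95 was undefined for the result or no
    HD limit exists — never silently False for missing data.
    """

    metric_result: MetricResult
    dsc_failed: bool
    hd_failed: Optional[bool]
    limits_used: ReferenceLimits


def compute_reference_limits(
    organ_name: str,
    dsc_values: Sequence[float],
    hd_values: Optional[Sequence[float]] = None,
) -> ReferenceLimits:
    """Estimate three-sigma limits from reference-cohort metric values.

    Mean is the arithmetic mean; SD uses the n−1 denominator.  The DSC
    lower limit ``mean − 3·SD`` is clamped at 0; an HD upper limit
    ``mean + 3·SD`` is added when HD values are supplied.
    """
    dsc = np.asarray(dsc_values, dtype=float)
    if dsc.size < 2:
        raise InsufficientDataError(
            f"{organ_name!r}: need >= 2 DSC values, got {dsc.size}"
        )
    if not np.all(np.isfinite(dsc)):
        raise DomainError(f"{organ_name!r}: non-finite DSC values")
    if np.any((dsc < 0) | (dsc > 1)):
        raise DomainError(f"{organ_name!r}: DSC values outside [0, 1]")
    mean = float(dsc.mean())
    sd = float(dsc.std(ddof=1))
    lower = max(mean - N_SIGMA * sd, 0.0)
    hd_mean = hd_sd = hd_upper = None
    if hd_values is not None:
        hd = np.asarray(hd_values, dtype=float)
        hd = hd[np.isfinite(hd)]
        if hd.size >= 2:
            hd_mean = float(hd.mean())
            hd_sd = float(hd.std(ddof=1))
            hd_upper = hd_mean + N_SIGMA * hd_sd
    return ReferenceLimits(
        organ_name=organ_name,
        dsc_mean=mean,
        dsc_sd=sd,
        dsc_lower_limit=lower,
        n_reference=int(dsc.size),
        hd_mean=hd_mean,
        hd_sd=hd_sd,
        hd_upper_limit=hd_upper,
    )


def flag_gross_failures(
    results: Iterable[MetricResult], limits: ReferenceLimits
) -> list[GrossFailureFlag]:
    """Flag results strictly below the DSC limit / above the HD limit.

    The inequalities are strict: a DSC exactly at the lower limit is not a
    failure ("below" the level flags).
    """
    flags = []
    for r in results:
        if r.organ_name != limits.organ_name:
            raise RoutingError(
                f"result for {r.organ_name!r} routed to limits of "
                f"{limits.organ_name!r}"
            )
        dsc_failed = r.dsc < limits.dsc_lower_limit
        if r.hd95_2d is None or limits.hd_upper_limit is None:
            hd_failed: Optional[bool] = None
        else:
            hd_failed = r.hd95_2d > limits.hd_upper_limit
        flags.append(
            GrossFailureFlag(
                metric_result=r,
                dsc_failed=dsc_failed,
                hd_failed=hd_failed,
                limits_used=limits,
            )
        )
    return flags


def _coerce_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        from .metrics import results_to_dataframe

        df = results_to_dataframe(list(data))
    if "organ" not in df.columns or "dsc" not in df.columns:
        raise ValueError("need columns 'organ' and 'dsc'")
    return df


class ContourQAModel:
    """Three-sigma contour-QA limits model.

    Parameters
    ----------
    data : DataFrame or iterable of MetricResult
        Reference-cohort metrics with columns ``organ`` and ``dsc`` and
        optionally ``hd95_2d`` (NaN where undefined).

    Examples
    --------
    >>> model = ContourQAModel.from_dataframe(ref_df)   # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(self, data):
        self.data = _coerce_frame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContourQAModel":
        return cls(df)

    @classmethod
    def from_metric_results(cls, results: Iterable[MetricResult]) -> "ContourQAModel":
        return cls(list(results))

    def fit(self) -> "ContourQAResults":
        """Estimate per-organ means, SDs and three-sigma control limits."""
        limits: dict[str, ReferenceLimits] = {}
        for organ, grp in self.data.groupby("organ", sort=True):
            hd = grp["hd95_2d"].to_numpy() if "hd95_2d" in grp.columns else None
            limits[str(organ)] = compute_reference_limits(
                str(organ), grp["dsc"].to_numpy(), hd_values=hd
            )
        return ContourQAResults(self, limits)


class ContourQAResults:
    """Fitted reference limits plus flagging/audit methods."""

    def __init__(self, model: ContourQAModel, limits: Mapping[str, ReferenceLimits]):
        self.model = model
        self.limits_ = dict(limits)

    @property
    def organs(self) -> list[str]:
        return sorted(self.limits_)

    @property
    def limits(self) -> pd.DataFrame:
        """Limits table, one row per organ, with standard errors.

        ``se_dsc_mean`` is ``SD/√n``; ``se_dsc_lower_limit`` uses the
        normal-theory delta approximation ``SD·√(1/n + 9/(2(n−1)))`` for
        the mean − 3·SD estimator.
        """
        rows = []
        for organ in self.organs:
            lim = self.limits_[organ]
            n = lim.n_reference
            se_mean = lim.dsc_sd / math.sqrt(n)
            se_limit = lim.dsc_sd * math.sqrt(1.0 / n + 9.0 / (2.0 * (n - 1)))
            rows.append(
                {
                    "organ": organ,
                    "dsc_mean": lim.dsc_mean,
                    "dsc_sd": lim.dsc_sd,
                    "dsc_lower_limit": lim.dsc_lower_limit,
                    "se_dsc_mean": se_mean,
                    "se_dsc_lower_limit": se_limit,
                    "hd_mean": np.nan if lim.hd_mean is None else lim.hd_mean,
                    "hd_sd": np.nan if lim.hd_sd is None else lim.hd_sd,
                    "hd_upper_limit": (
                        np.nan if lim.hd_upper_limit is None else lim.hd_upper_limit
                    ),
                    "n_reference": n,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-organ limits table."""
        df = self.limits
        lines = [
            "Contour QA reference limits (three-sigma)",
            "=" * 78,
            f"{'organ':<16}{'n':>4}{'DSC mean':>10}{'SD':>8}"
            f"{'lower limit':>13}{'(se)':>9}{'HD95 upper':>12}",
            "-" * 78,
        ]
        for _, r in df.iterrows():
            hd = "" if np.isnan(r["hd_upper_limit"]) else f"{r['hd_upper_limit']:.1f} mm"
            lines.append(
                f"{r['organ']:<16}{int(r['n_reference']):>4}"
                f"{r['dsc_mean']:>10.3f}{r['dsc_sd']:>8.3f}"
                f"{r['dsc_lower_limit']:>13.3f}{r['se_dsc_lower_limit']:>9.3f}"
                f"{hd:>12}"
            )
        lines.append("=" * 78)
        lines.append("gross failure: DSC strictly below the lower limit")
        return "\n".join(lines)

    def flag(self, results: Iterable[MetricResult]) -> list[GrossFailureFlag]:
        """Flag a test cohort of metric results organ by organ."""
        by_organ: dict[str, list[MetricResult]] = {}
        ordered = list(results)
        for r in ordered:
            if r.organ_name not in self.limits_:
                raise RoutingError(f"no fitted limits for organ {r.organ_name!r}")
            by_organ.setdefault(r.organ_name, []).append(r)
        flags_by_id = {}
        for organ, rs in by_organ.items():
            for f in flag_gross_failures(rs, self.limits_[organ]):
                flags_by_id[id(f.metric_result)] = f
        return [flags_by_id[id(r)] for r in ordered]

    def audit(self, results, annotations, n_evaluated_per_organ):
        """Flag, apply expert review, and summarise a test cohort."""
        from .report import summarize_cohort
        from .review import apply_review

        flags = self.flag(results)
        records = apply_review(flags, annotations)
        return summarize_cohort(records, n_evaluated_per_organ)

    # ------------------------------------------------------------ persistence
    def to_csv(self, path) -> None:
        self.limits.to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.limits.to_dict(orient="records")))

    @classmethod
    def from_csv(cls, path) -> "ContourQAResults":
        df = pd.read_csv(path)
        limits = {}
        for _, r in df.iterrows():
            limits[str(r["organ"])] = ReferenceLimits(
                organ_name=str(r["organ"]),
                dsc_mean=float(r["dsc_mean"]),
                dsc_sd=float(r["dsc_sd"]),
                dsc_lower_limit=float(r["dsc_lower_limit"]),
                n_reference=int(r["n_reference"]),
                hd_mean=None if pd.isna(r.get("hd_mean")) else float(r["hd_mean"]),
                hd_sd=None if pd.isna(r.get("hd_sd")) else float(r["hd_sd"]),
                hd_upper_limit=(
                    None
                    if pd.isna(r.get("hd_upper_limit"))
                    else float(r["hd_upper_limit"])
                ),
            )
        model = ContourQAModel(pd.DataFrame({"organ": [], "dsc": []}))
        return cls(model, limits)
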