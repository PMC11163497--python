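"""Synthetic contour phantoms and metric-level cohort simulation.

No patient dataset accompanies the QA procedure, so this module generates
everything the pipeline needs:

* geometric organ-like contour phantoms on a 2 mm-slice CT-like grid
  (ellipsoids for brainstem/parotid-like structures, a C-shaped horseshoe
  for the mandible, cylinders for analytic tests);
* controlled failure-mode perturbations mirroring the three observed
  contour-level failure archetypes — a rigid axial roll (setup surrogate,
  ≈7°), an attached disjoint component (surgical-plate surrogate), and
  superior-inferior truncation (dental-artefact surrogate) — plus radial
  boundary noise as the generic delineation-variability model;
* metric-level DSC cohorts drawn from truncated normal distributions with
  reference means/SDs of 0.81±0.06 (brainstem), 0.91±0.02 (mandible),
  0.76±0.06 (left parotid) and 0.74±0.08 (right parotid), optionally
  contaminated with gross failures.

The failure archetypes are geometric surrogates: the underlying causes
(patient setup, surgery, CT artefacts) act on the image, and only their
contour-level consequences are modelled here — sufficient to exercise
every pipeline stage.

Baseline auto contours perturb the gold contour by radial boundary noise
with a per-patient amplitude drawn uniformly from 0.3–0.9 mm.  A
near-uniform DSC distribution has bounded support within ±√3 SD of its
mean, so a three-sigma lower limit calibrated on the same distribution
cannot flag failure-free pairs; injected failures are the only flags, and
end-to-end audits recover injection counts exactly for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateStructureError
from .geometry import ContourSlice, ContourStack, StructurePair
from .review import ReviewAnnotation

__all__ = [
    "ORGAN_DSC_REFERENCE",
    "ORGAN_ARCHETYPES",
    "PhantomSpec",
    "make_phantom",
    "PerturbationSpec",
    "perturb",
    "CohortSimParams",
    "simulate_metric_cohort",
    "PhantomCohort",
    "generate_phantom_cohort",
    "DEFAULT_INJECTION_PLAN",
]

#: Reference-cohort DSC (mean, SD) per organ, from a 50-patient calibration.
ORGAN_DSC_REFERENCE: dict[str, tuple[float, float]] = {
    "brainstem": (0.81, 0.06),
    "mandible": (0.91, 0.02),
    "parotid_l": (0.76, 0.06),
    "parotid_r": (0.74, 0.08),
}

PERTURBATION_KINDS = ("truncate_si", "roll", "attach_component", "boundary_noise")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of an organ-like contour phantom.

    ``semi_axes`` (a, b, c) applies to the ellipsoid archetype (in-plane
    semi-axes a, b; superior-inferior semi-axis c); ``radii`` is (r,) for
    the cylinder and (outer, inner) for the horseshoe.  All mm.
    """

    organ_archetype: str  # "ellipsoid" | "horseshoe" | "cylinder"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: Optional[tuple[float, float, float]] = None
    radii: Optional[tuple[float, ...]] = None
    n_slices: int = 12
    slice_thickness: float = 2.0
    vertices_per_contour: int = 64
    gap_angle_deg: float = 70.0  # horseshoe opening

    def __post_init__(self):
        if self.organ_archetype not in ("ellipsoid", "horseshoe", "cylinder"):
            raise ValueError(f"unknown archetype {self.organ_archetype!r}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.vertices_per_contour < 8:
            raise ValueError("vertices_per_contour must be >= 8")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if self.organ_archetype == "ellipsoid":
            if self.semi_axes is None or any(v <= 0 for v in self.semi_axes):
                raise ValueError("ellipsoid needs positive semi_axes (a, b, c)")
            half_extent = (self.n_slices - 1) / 2 * self.slice_thickness
            if half_extent >= self.semi_axes[2]:
                raise ValueError("slice stack exceeds the ellipsoid's z semi-axis")
        elif self.organ_archetype == "cylinder":
            if self.radii is None or len(self.radii) != 1 or self.radii[0] <= 0:
                raise ValueError("cylinder needs radii=(r,) with r > 0")
        else:  # horseshoe
            if (
                self.radii is None
                or len(self.radii) != 2
                or not 0 < self.radii[1] < self.radii[0]
            ):
                raise ValueError("horseshoe needs radii=(outer, inner), 0 < inner < outer")


def _slice_zs(spec: PhantomSpec) -> np.ndarray:
    offs = (np.arange(spec.n_slices) - (spec.n_slices - 1) / 2) * spec.slice_thickness
    return spec.center[2] + offs


def make_phantom(spec: PhantomSpec, seed: int = 0, organ_name: str = "phantom") -> ContourStack:
    """Build a contour phantom; deterministic given ``(spec, seed)``.

    The seed only rotates the vertex starting phase, so distinct patients
    do not share vertex positions exactly.
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2 * np.pi)
    x0, y0, _ = spec.center
    n = spec.vertices_per_contour
    slices = []
    for z in _slice_zs(spec):
        if spec.organ_archetype == "cylinder":
            theta = phase + 2 * np.pi * np.arange(n) / n
            r = spec.radii[0]
            poly = np.column_stack([x0 + r * np.cos(theta), y0 + r * np.sin(theta)])
        elif spec.organ_archetype == "ellipsoid":
            a, b, c = spec.semi_axes
            f = np.sqrt(max(1.0 - ((z - spec.center[2]) / c) ** 2, 0.0))
            theta = phase + 2 * np.pi * np.arange(n) / n
            poly = np.column_stack(
                [x0 + a * f * np.cos(theta), y0 + b * f * np.sin(theta)]
            )
        else:  # horseshoe: annular sector with an anterior opening
            outer, inner = spec.radii
            gap = np.deg2rad(spec.gap_angle_deg)
            n_arc = max(n // 2, 8)
            ang = np.linspace(gap / 2, 2 * np.pi - gap / 2, n_arc) + phase * 0
            outer_arc = np.column_stack(
                [x0 + outer * np.cos(ang), y0 + outer * np.sin(ang)]
            )
            inner_arc = np.column_stack(
                [x0 + inner * np.cos(ang[::-1]), y0 + inner * np.sin(ang[::-1])]
            )
            poly = np.vstack([outer_arc, inner_arc])
        slices.append(ContourSlice(z=float(z), polygons=(poly,)))
    return ContourStack(organ_name=organ_name, slices=tuple(slices))


@dataclass(frozen=True)
class PerturbationSpec:
    """One contour-level failure-mode perturbation.

    ``parameters`` are kind-specific:

    * ``truncate_si`` — ``k`` slices removed from the ``end``
      ("superior", default, or "inferior");
    * ``roll`` — ``angle_deg`` rotation about ``pivot`` (x, y) mm;
    * ``attach_component`` — disjoint circle of ``radius`` at ``center``
      (x, y), on all slices unless ``slice_indices`` given;
    * ``boundary_noise`` — seeded radial Gaussian vertex displacement of
      SD ``amplitude`` mm about each polygon centroid.
    """

    kind: str
    parameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


def _rotate(poly: np.ndarray, angle_deg: float, pivot: tuple[float, float]) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return (poly - pivot) @ rot.T + pivot


def perturb(stack: ContourStack, p: PerturbationSpec) -> ContourStack:
    """Apply one failure-mode perturbation; deterministic given the spec."""
    params = dict(p.parameters)
    if p.kind == "truncate_si":
        k = int(params.get("k", 1))
        end = params.get("end", "superior")
        if k >= stack.n_slices:
            raise DegenerateStructureError(
                f"cannot remove {k} of {stack.n_slices} slices"
            )
        if k <= 0:
            return stack
        kept = stack.slices[:-k] if end == "superior" else stack.slices[k:]
        return ContourStack(organ_name=stack.organ_name, slices=kept)

    if p.kind == "roll":
        angle = float(params.get("angle_deg", 7.0))
        if "pivot" in params:
            pivot = tuple(params["pivot"])  # type: ignore[arg-type]
        else:
            pts = np.vstack([pl for s in stack.slices for pl in s.polygons])
            pivot = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        slices = tuple(
            ContourSlice(
                z=s.z, polygons=tuple(_rotate(pl, angle, pivot) for pl in s.polygons)
            )
            for s in stack.slices
        )
        return ContourStack(organ_name=stack.organ_name, slices=slices)

    if p.kind == "attach_component":
        cx, cy = params["center"]  # type: ignore[misc]
        radius = float(params["radius"])  # type: ignore[arg-type]
        n_vertices = int(params.get("n_vertices", 24))
        idx = params.get("slice_indices")
        indices = set(range(stack.n_slices)) if idx is None else set(idx)
        theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
        blob = np.column_stack(
            [cx + radius * np.cos(theta), cy + radius * np.sin(theta)]
        )
        slices = tuple(
            ContourSlice(z=s.z, polygons=s.polygons + (blob.copy(),))
            if i in indices
            else s
            for i, s in enumerate(stack.slices)
        )
        return ContourStack(organ_name=stack.organ_name, slices=slices)

    # boundary_noise
    amplitude = float(params.get("amplitude", 0.5))
    rng = np.random.default_rng(p.seed)
    slices = []
    for s in stack.slices:
        polys = []
        for pl in s.polygons:
            centroid = pl.mean(axis=0)
            rel = pl - centroid
            r = np.hypot(rel[:, 0], rel[:, 1])
            safe_r = np.where(r == 0, 1.0, r)
            noise = rng.normal(0.0, amplitude, size=len(pl))
            scale = (r + noise).clip(min=0.1) / safe_r
            polys.append(centroid + rel * scale[:, None])
        slices.append(ContourSlice(z=s.z, polygons=tuple(polys)))
    return ContourStack(organ_name=stack.organ_name, slices=tuple(slices))


# --------------------------------------------------------- metric-level cohort

@dataclass(frozen=True)
class CohortSimParams:
    """Parameters for a metric-level (DSC-only) cohort simulation.

    Per organ, failure-free DSC values follow Normal(mean, sd) truncated
    to (0, 1]; with probability ``gross_failure_prob`` a value is replaced
    by Uniform(``failure_dsc_range``), which must lie wholly below
    mean − 3·SD so injected failures are separable by construction.
    """

    organ_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ORGAN_DSC_REFERENCE)
    )
    n_patients: int = 500
    gross_failure_prob: float = 0.0
    failure_dsc_range: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gross_failure_prob <= 1.0:
            raise ValueError("gross_failure_prob must be in [0, 1]")
        lo, hi = self.failure_dsc_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("failure_dsc_range must be within [0, 1]")
        if self.gross_failure_prob > 0:
            for organ, (mean, sd) in self.organ_params.items():
                if hi >= mean - 3 * sd:
                    raise ValueError(
                        f"failure_dsc_range must lie below mean - 3*SD for {organ!r}"
                    )


def truncated_normal(mean: float, sd: float, lower: float = 0.0, upper: float = 1.0):
    """Frozen scipy truncated-normal on (lower, upper] for DSC draws."""
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def simulate_metric_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Draw a per-organ DSC cohort with ground-truth failure labels.

    Returns a DataFrame with columns ``organ``, ``patient_id``, ``dsc``
    and boolean ``is_failure``; deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for organ in sorted(params.organ_params):
        mean, sd = params.organ_params[organ]
        dist = truncated_normal(mean, sd)
        dsc = dist.rvs(size=params.n_patients, random_state=rng)
        fail = rng.random(params.n_patients) < params.gross_failure_prob
        lo, hi = params.failure_dsc_range
        dsc[fail] = rng.uniform(lo, hi, size=int(fail.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "organ": organ,
                    "patient_id": [f"sim-{organ}-{i:04d}" for i in range(params.n_patients)],
                    "dsc": dsc,
                    "is_failure": fail,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------ phantom cohorts

#: Organ archetype geometry used for contour-level cohorts (mm).
ORGAN_ARCHETYPES: dict[str, PhantomSpec] = {
    "brainstem": PhantomSpec(
        "ellipsoid", center=(0.0, 30.0, 0.0), semi_axes=(10.0, 12.0, 16.0), n_slices=14
    ),
    "mandible": PhantomSpec(
        "horseshoe", center=(0.0, -20.0, 0.0), radii=(30.0, 22.0), n_slices=10
    ),
    "parotid_l": PhantomSpec(
        "ellipsoid", center=(45.0, 0.0, 0.0), semi_axes=(12.0, 15.0, 20.0), n_slices=16
    ),
    "parotid_r": PhantomSpec(
        "ellipsoid", center=(-45.0, 0.0, 0.0), semi_axes=(12.0, 15.0, 20.0), n_slices=16
    ),
}

#: Injected gross failures per organ in the default 500-patient test cohort:
#: counts per review verdict (censored = suboptimal gold contour).
DEFAULT_INJECTION_PLAN: dict[str, dict[str, int]] = {
    "brainstem": {"censored_suboptimal_manual": 2, "setup": 2},
    "mandible": {"censored_suboptimal_manual": 9, "anatomy": 8, "artefacts": 3},
    "parotid_l": {"censored_suboptimal_manual": 6, "anatomy": 5, "unknown": 2},
    "parotid_r": {
        "censored_suboptimal_manual": 3,
        "setup": 1,
        "anatomy": 2,
        "artefacts": 1,
    },
}

#: Baseline delineation-noise amplitude range (mm): uniform per patient.
BASELINE_NOISE_RANGE = (0.3, 0.9)


@dataclass
class PhantomCohort:
    """A generated reference + test cohort of contour pairs."""

    reference_pairs: list[StructurePair]
    test_pairs: list[StructurePair]
    manifest: pd.DataFrame
    annotations: list[ReviewAnnotation]
    seed: int


def _failure_perturbation(
    verdict: str, spec: PhantomSpec, rng: np.random.Generator
) -> PerturbationSpec:
    """Map a review verdict to a gross contour perturbation."""
    seed = int(rng.integers(0, 2**31 - 1))
    if verdict == "setup":
        # rigid axial roll about a pivot well below the structure (~7 deg)
        pivot = (spec.center[0], spec.center[1] - 90.0)
        return PerturbationSpec("roll", {"angle_deg": 7.0, "pivot": pivot}, seed=seed)
    if verdict == "anatomy":
        # attached disjoint component (surgical-plate surrogate)
        if spec.organ_archetype == "horseshoe":
            size = spec.radii[0] - spec.radii[1]
            cx = spec.center[0] + spec.radii[0] + size + 4.0
            radius = 1.6 * size
        else:
            size = max(spec.semi_axes[0], spec.semi_axes[1])
            cx = spec.center[0] + size + 0.9 * size + 4.0
            radius = 0.9 * size
        return PerturbationSpec(
            "attach_component", {"center": (cx, spec.center[1]), "radius": radius}, seed=seed
        )
    if verdict in ("artefacts", "censored_suboptimal_manual"):
        # superior-inferior truncation (dental-artefact surrogate)
        return PerturbationSpec("truncate_si", {"k": 5, "end": "superior"}, seed=seed)
    # unknown: gross, structureless delineation noise
    return PerturbationSpec("boundary_noise", {"amplitude": 4.0}, seed=seed)


def _make_pair(
    organ: str,
    spec: PhantomSpec,
    patient_id: str,
    rng: np.random.Generator,
    verdict: Optional[str],
) -> tuple[StructurePair, dict]:
    """One gold/auto pair with baseline noise and an optional injected failure."""
    phantom_seed = int(rng.integers(0, 2**31 - 1))
    gold = make_phantom(spec, seed=phantom_seed, organ_name=organ)
    amplitude = float(rng.uniform(*BASELINE_NOISE_RANGE))
    noise_seed = int(rng.integers(0, 2**31 - 1))
    auto = perturb(
        gold,
        PerturbationSpec("boundary_noise", {"amplitude": amplitude}, seed=noise_seed),
    )
    injected_kind = ""
    if verdict is not None:
        pspec = _failure_perturbation(verdict, spec, rng)
        injected_kind = pspec.kind
        if verdict == "censored_suboptimal_manual":
            gold = perturb(gold, pspec)  # the *manual* contour is the bad one
        else:
            auto = perturb(auto, pspec)
    pair = StructurePair(patient_id=patient_id, organ_name=organ, gold=gold, auto=auto)
    row = {
        "patient_id": patient_id,
        "organ": organ,
        "injected_verdict": verdict or "",
        "injected_kind": injected_kind,
        "noise_amplitude_mm": amplitude,
        "phantom_seed": phantom_seed,
    }
    return pair, row


def generate_phantom_cohort(
    organs: Sequence[str] = tuple(ORGAN_ARCHETYPES),
    n_reference: int = 50,
    n_test: int = 500,
    injection_plan: Optional[Mapping[str, Mapping[str, int]]] = None,
    seed: int = 0,
    out_dir=None,
) -> PhantomCohort:
    """Generate a full reference + test cohort of contour phantom pairs.

    The reference cohort (default 50 pairs per organ) is failure-free;
    the test cohort (default 500 per organ) receives the injected
    failures of ``injection_plan`` (verdict → count per organ) at
    rng-chosen patient positions.  Annotations are emitted for every
    injected failure, standing in for the expert review.  With
    ``out_dir`` the cohort is also written as contour-json files plus
    ``manifest.csv`` and ``annotations.csv``.
    """
    if injection_plan is None:
        injection_plan = {
            o: DEFAULT_INJECTION_PLAN.get(o, {}) for o in organs
        }
    rng = np.random.default_rng(seed)
    reference_pairs: list[StructurePair] = []
    test_pairs: list[StructurePair] = []
    manifest_rows: list[dict] = []
    annotations: list[ReviewAnnotation] = []

    for organ in organs:
        spec = ORGAN_ARCHETYPES[organ]
        for i in range(n_reference):
            pair, row = _make_pair(organ, spec, f"ref-{organ}-{i:04d}", rng, None)
            row["cohort"] = "reference"
            reference_pairs.append(pair)
            manifest_rows.append(row)

        plan = dict(injection_plan.get(organ, {}))
        n_injected = sum(plan.values())
        if n_injected > n_test:
            raise ValueError(f"{organ!r}: injection plan exceeds cohort size")
        fail_idx = rng.choice(n_test, size=n_injected, replace=False)
        verdict_by_idx: dict[int, str] = {}
        pos = 0
        for verdict, count in plan.items():
            for j in range(count):
                verdict_by_idx[int(fail_idx[pos])] = verdict
                pos += 1
        for i in range(n_test):
            verdict = verdict_by_idx.get(i)
            pid = f"test-{organ}-{i:04d}"
            pair, row = _make_pair(organ, spec, pid, rng, verdict)
            row["cohort"] = "test"
            test_pairs.append(pair)
            manifest_rows.append(row)
            if verdict is not None:
                annotations.append(
                    ReviewAnnotation(
                        patient_id=pid,
                        organ_name=organ,
                        verdict=verdict,
                        note=f"injected:{row['injected_kind']}",
                    )
                )

    manifest = pd.DataFrame(manifest_rows)
    cohort = PhantomCohort(
        reference_pairs=reference_pairs,
        test_pairs=test_pairs,
        manifest=manifest,
        annotations=annotations,
        seed=seed,
    )
    if out_dir is not None:
        _write_cohort(cohort, out_dir)
    return cohort


def _write_cohort(cohort: PhantomCohort, out_dir) -> None:
    from .io import write_contour_json
    from .review import write_annotations_csv

    out = Path(out_dir)
    for sub, pairs in (
        ("reference", cohort.reference_pairs),
        ("test", cohort.test_pairs),
    ):
        d = out / sub
        d.mkdir(parents=True, exist_ok=True)
        for pair in pairs:
            write_contour_json(pair.gold, d / f"{pair.patient_id}_gold.json")
            write_contour_json(pair.auto, d / f"{pair.patient_id}_auto.json")
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    write_annotations_csv(cohort.annotations, out / "annotations.csv")
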