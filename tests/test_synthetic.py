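"""Phantom generation, failure-mode perturbations, cohort simulation."""

import numpy as np
import pandas as pd
import pytest

from segqa.geometry import fit_grid, rasterize_contour_stack
from segqa.metrics import dsc_3d, evaluate_pair, hd95_2d
from segqa.model import compute_reference_limits
from segqa.synthetic import (
    ORGAN_DSC_REFERENCE,
    CohortSimParams,
    PerturbationSpec,
    PhantomSpec,
    generate_phantom_cohort,
    make_phantom,
    perturb,
    simulate_metric_cohort,
    truncated_normal,
)
from segqa._exceptions import DegenerateStructureError

from conftest import shoelace_area


class TestMakePhantom:
    def test_cylinder_slice_area(self):
        n_vert = 64
        spec = PhantomSpec("cylinder", radii=(10.0,), n_slices=20, vertices_per_contour=n_vert)
        stack = make_phantom(spec, seed=0)
        # inscribed regular polygon area: pi r^2 * (n/2pi) sin(2pi/n)
        expected = 100 * n_vert / 2 * np.sin(2 * np.pi / n_vert)
        for s in stack.slices:
            assert shoelace_area(s.polygons[0]) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(np.pi * 100, rel=0.01)

    def test_ellipsoid_equatorial_radius(self):
        spec = PhantomSpec("ellipsoid", semi_axes=(10.0, 10.0, 16.0), n_slices=15)
        stack = make_phantom(spec, seed=0)
        equator = stack.slices[7]  # z = 0 by construction
        assert equator.z == 0.0
        r = np.hypot(*(equator.polygons[0].T))
        np.testing.assert_allclose(r, 10.0, atol=1e-9)

    def test_determinism(self):
        spec = PhantomSpec("horseshoe", radii=(30.0, 22.0), n_slices=5)
        a = make_phantom(spec, seed=9)
        b = make_phantom(spec, seed=9)
        for sa, sb in zip(a.slices, b.slices):
            np.testing.assert_array_equal(sa.polygons[0], sb.polygons[0])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PhantomSpec("cylinder", radii=(-1.0,))
        with pytest.raises(ValueError):
            PhantomSpec("ellipsoid", semi_axes=(10, 10, 5), n_slices=20)  # exceeds c
        with pytest.raises(ValueError):
            PhantomSpec("cylinder", radii=(10.0,), vertices_per_contour=4)


class TestPerturb:
    def test_zero_roll_is_identity(self, cylinder20):
        rolled = perturb(cylinder20, PerturbationSpec("roll", {"angle_deg": 0.0}))
        for sa, sb in zip(cylinder20.slices, rolled.slices):
            np.testing.assert_allclose(sa.polygons[0], sb.polygons[0], atol=1e-12)

    def test_truncate_closed_form_dsc(self, cylinder20):
        for k in (1, 5, 10):
            trunc = perturb(cylinder20, PerturbationSpec("truncate_si", {"k": k}))
            grid = fit_grid([cylinder20])
            d = dsc_3d(
                rasterize_contour_stack(cylinder20, grid),
                rasterize_contour_stack(trunc, grid),
            )
            assert d == pytest.approx(2 * (20 - k) / (40 - k), abs=1e-12)

    def test_truncate_degenerate(self, cylinder20):
        with pytest.raises(DegenerateStructureError):
            perturb(cylinder20, PerturbationSpec("truncate_si", {"k": 20}))

    def test_truncate_inferior_end(self, cylinder20):
        trunc = perturb(cylinder20, PerturbationSpec("truncate_si", {"k": 3, "end": "inferior"}))
        assert trunc.n_slices == 17
        assert trunc.z_positions[0] == cylinder20.z_positions[3]

    def test_attach_component_adds_second_polygon(self, cylinder20):
        blob = PerturbationSpec("attach_component", {"center": (25.0, 0.0), "radius": 3.0})
        attached = perturb(cylinder20, blob)
        assert all(len(s.polygons) == 2 for s in attached.slices)
        grid = fit_grid([cylinder20, attached])
        d = dsc_3d(
            rasterize_contour_stack(cylinder20, grid),
            rasterize_contour_stack(attached, grid),
        )
        assert d < 1.0

    def test_small_attachment_fails_hd_not_dsc(self, cylinder20):
        # matched SI extent, small added component far from the organ:
        # DSC stays near 1, HD95 jumps to the component's distance scale
        blob = PerturbationSpec("attach_component", {"center": (30.0, 0.0), "radius": 3.0})
        attached = perturb(cylinder20, blob)
        grid = fit_grid([cylinder20, attached])
        d = dsc_3d(
            rasterize_contour_stack(cylinder20, grid),
            rasterize_contour_stack(attached, grid),
        )
        hd, *_ = hd95_2d(cylinder20, attached)
        assert d > 0.95
        assert hd > 10.0

    def test_boundary_noise_seeded(self, cylinder20):
        p = PerturbationSpec("boundary_noise", {"amplitude": 1.0}, seed=4)
        a, b = perturb(cylinder20, p), perturb(cylinder20, p)
        for sa, sb in zip(a.slices, b.slices):
            np.testing.assert_array_equal(sa.polygons[0], sb.polygons[0])
        c = perturb(cylinder20, PerturbationSpec("boundary_noise", {"amplitude": 1.0}, seed=5))
        assert not np.allclose(a.slices[0].polygons[0], c.slices[0].polygons[0])


class TestSimulateCohort:
    def test_no_failures_when_prob_zero(self):
        df = simulate_metric_cohort(CohortSimParams(n_patients=100, seed=1))
        assert not df["is_failure"].any()
        assert len(df) == 400  # 4 organs
        assert df["dsc"].between(0, 1).all()

    def test_deterministic_per_seed(self):
        a = simulate_metric_cohort(CohortSimParams(n_patients=50, seed=3))
        b = simulate_metric_cohort(CohortSimParams(n_patients=50, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_failure_range_must_sit_below_limits(self):
        with pytest.raises(ValueError):
            CohortSimParams(gross_failure_prob=0.01, failure_dsc_range=(0.1, 0.9))

    def test_injected_failures_fully_recallable(self):
        # failure DSC range lies wholly below every reference lower limit,
        # so flagging with the reference limits recalls every injection
        params = CohortSimParams(
            n_patients=2000, gross_failure_prob=0.012, failure_dsc_range=(0.1, 0.4), seed=8
        )
        df = simulate_metric_cohort(params)
        recalled = 0
        total = 0
        for organ, (mean, sd) in ORGAN_DSC_REFERENCE.items():
            sub = df[df["organ"] == organ]
            flagged = sub["dsc"] < mean - 3 * sd
            total += int(sub["is_failure"].sum())
            recalled += int((flagged & sub["is_failure"]).sum())
        assert total > 0
        assert recalled / total >= 0.99

    def test_tail_fraction_matches_analytic(self):
        mean, sd = ORGAN_DSC_REFERENCE["brainstem"]
        df = simulate_metric_cohort(
            CohortSimParams(organ_params={"brainstem": (mean, sd)}, n_patients=300_000, seed=12)
        )
        tail = truncated_normal(mean, sd).cdf(mean - 3 * sd)
        frac = (df["dsc"] < mean - 3 * sd).mean()
        se = np.sqrt(tail * (1 - tail) / len(df))
        assert abs(frac - tail) < 4 * se + 1e-12


class TestPhantomCohort:
    def test_manifest_and_annotations_consistent(self):
        cohort = generate_phantom_cohort(
            organs=("brainstem",), n_reference=3, n_test=10, seed=5
        )
        assert len(cohort.reference_pairs) == 3
        assert len(cohort.test_pairs) == 10
        test_rows = cohort.manifest.query("cohort == 'test'")
        injected = test_rows[test_rows["injected_verdict"] != ""]
        assert len(injected) == 4  # brainstem plan: 2 censored + 2 setup
        assert {a.patient_id for a in cohort.annotations} == set(injected["patient_id"])

    def test_cohort_written_to_disk(self, tmp_path):
        generate_phantom_cohort(
            organs=("brainstem",), n_reference=2, n_test=4,
            injection_plan={"brainstem": {"setup": 1}}, seed=5, out_dir=tmp_path,
        )
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "annotations.csv").exists()
        assert len(list((tmp_path / "reference").glob("*.json"))) == 4
        assert len(list((tmp_path / "test").glob("*.json"))) == 8

    def test_injected_failures_separate_from_baseline(self):
        # every injected failure must sit clearly below the baseline DSC
        # band so three-sigma flagging recovers injections exactly
        cohort = generate_phantom_cohort(
            organs=("parotid_l",), n_reference=8, n_test=12,
            injection_plan={"parotid_l": {"anatomy": 2, "unknown": 1}}, seed=21,
        )
        ref = [evaluate_pair(p) for p in cohort.reference_pairs]
        test = [evaluate_pair(p) for p in cohort.test_pairs]
        lim = compute_reference_limits("parotid_l", [r.dsc for r in ref])
        injected_ids = {a.patient_id for a in cohort.annotations}
        flagged_ids = {r.patient_id for r in test if r.dsc < lim.dsc_lower_limit}
        assert flagged_ids == injected_ids
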