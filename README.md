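# segqa

Statistical quality assurance for AI auto-segmented organ-at-risk (OAR)
contours in radiotherapy treatment planning.

Commercial deep-learning systems now delineate OARs automatically, but they
fail occasionally and grossly — a rolled patient setup, post-surgical
anatomy, or dental CT artefacts can produce a contour that is badly wrong.
Because such gross failures are rare (on the order of 1%), catching them by
100% manual inspection is both costly and error-prone. `segqa` implements a
statistical alternative: quantify normal agreement between expert ("gold
standard") and auto-generated contours on a reference cohort, then audit
every new case against a control limit.

## Method

For each patient and organ, two metrics compare the gold contour *A* with
the auto contour *B*:

* **3D Dice similarity coefficient** — volume overlap on voxelised
  structures,

  DSC = 2·|A ∩ B| / (|A| + |B|) ∈ [0, 1];

* **slice-wise 2D 95% Hausdorff distance (HD95)** — on every axial slice
  where *both* structures have a contour, each boundary is resampled at a
  fixed arc-length step and all directed point-to-boundary distances (both
  directions) are pooled across shared slices; HD95 is the 95th percentile.
  Slices with only one contour contribute nothing, which is why
  superior–inferior truncation failures can evade HD95 while collapsing the
  DSC — a blind spot the package demonstrates and tests explicitly.

From a reference cohort the per-organ mean μ and sample SD σ of DSC are
estimated and a **gross failure** is any audited case with

DSC < μ − 3σ

(one-sided three-sigma rule; ≈99.7% of in-control results lie above the
limit). An analogous upper limit μ + 3σ applies to HD95. Flagged cases go
to expert review: flags caused by a suboptimal *manual* contour are
**censored** (removed from the failure numerator, not the denominator);
true failures are classified as setup / anatomy / artefacts / unknown, and
per-organ true-failure rates are reported.

Because no patient data ship with the package, `segqa.synthetic` generates
organ-like contour phantoms (ellipsoids, a horseshoe mandible surrogate)
on a 2 mm-slice grid, with seeded perturbations reproducing the observed
failure archetypes: an ≈7° axial roll, an attached disjoint component
(surgical-plate surrogate), superior–inferior truncation, and boundary
noise. Metric-level cohorts can also be simulated directly from truncated
normal DSC distributions.

## Worked example

Calibrate on a synthetic 20-pair reference cohort per organ, then audit a
100-pair test cohort with six injected failures:

```python
from segqa.synthetic import generate_phantom_cohort
from segqa.metrics import evaluate_pair
from segqa.model import ContourQAModel
from segqa.review import apply_review
from segqa.report import summarize_cohort, format_report

cohort = generate_phantom_cohort(
    n_reference=20, n_test=100,
    injection_plan={"brainstem": {"censored_suboptimal_manual": 1, "setup": 1},
                    "mandible": {"anatomy": 2, "artefacts": 1},
                    "parotid_l": {"unknown": 1},
                    "parotid_r": {"censored_suboptimal_manual": 1}},
    seed=7)

ref = [evaluate_pair(p) for p in cohort.reference_pairs]
results = ContourQAModel.from_metric_results(ref).fit()
print(results.summary())

test = [evaluate_pair(p) for p in cohort.test_pairs]
records = apply_review(results.flag(test), cohort.annotations)
print(format_report(summarize_cohort(records, 100)).to_string())
```

prints

```
Contour QA reference limits (three-sigma)
==============================================================================
organ              n  DSC mean      SD  lower limit     (se)  HD95 upper
------------------------------------------------------------------------------
brainstem         20     0.961   0.014        0.920    0.007      1.7 mm
mandible          20     0.950   0.013        0.911    0.007      1.6 mm
parotid_l         20     0.967   0.007        0.945    0.004      1.5 mm
parotid_r         20     0.970   0.009        0.942    0.005      1.5 mm
==============================================================================
gross failure: DSC strictly below the lower limit

                                      brainstem mandible parotid_l parotid_r
Failures                                      2        3         1         1
Censored (sub-optimal manual contour)         1        0         0         1
Setup position                                1        0         0         0
Anatomical                                    0        2         0         0
Image artefacts                               0        1         0         0
Unknown                                       0        0         1         0
True failures                                 1        3         1         0
True failure rate                          1.0%     3.0%      1.0%      0.0%
```

Every injected failure — and nothing else — was flagged; the one case whose
*gold* contour was degraded is censored rather than counted as a true
failure of the auto-segmentation.

The table's columns mirror the audit workflow: `Failures` is everything the
three-sigma rule flagged, the censored row removes suboptimal-gold cases,
the four middle rows break true failures down by reviewed cause, and the
rate divides true failures by the full per-organ cohort size.

The same pipeline is available from the shell:

```bash
segqa generate --out cohort --n-reference 50 --n-test 500 --seed 1
segqa calibrate --cohort cohort --out calib
segqa audit --cohort cohort --limits calib/limits.csv \
            --annotations cohort/annotations.csv --out audit
```

`audit` exits with status 3 when gross failures are present and writes
`metrics.csv`, `flags.csv`, `report.csv` (the 8-row table above),
`plot_data.csv` (per-patient DSC with the failure line, for control
charts) and `summary.json`.

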