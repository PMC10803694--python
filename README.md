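# lungdeform

Quantitative analysis of regional lung deformation from paired
inspiration/expiration 3D volumes, built around deformable registration and
Jacobian-determinant maps.

## The problem

In fibrotic lung disease (e.g., idiopathic pulmonary fibrosis, IPF) the
parenchyma stiffens, most prominently in the peripheral and basal lung, and
regional deformation between respiratory phases shrinks long before global
lung volumes collapse. Given a breath-hold image pair per subject —
inspiration and expiration — deformable registration recovers the dense
correspondence field, and the Jacobian determinant of that field is a
voxelwise map of local volume change. This package implements the full
analysis for researchers working with paired respiratory-phase volumes
(UTE MRI, CT) plus a synthetic breathing-lung cohort with closed-form
ground-truth deformation so that every stage is testable without any
clinical data.

## The method

For each subject, with inspiration as moving and expiration as fixed image:

1. **Preprocess** — isotropic resampling, threshold lung segmentation,
   dilation of the lung mask (Euclidean ball, 10 mm) into a peri-lung ROI.
2. **Elastic registration** — a displacement field `u` on the expiration
   grid pointing into inspiration space (multi-resolution diffeomorphic
   demons; or an external tool's field; or, for validation, the synthetic
   model's exact field). QC: IoU of the registered inspiratory lung mask
   against the expiratory mask, and residual distances DA/DB of two
   landmark categories.
3. **Jacobian chain** — per voxel

   `JAC = det(I + ∇u)`   (>1 stretch, <1 shrinkage)

   `JAC-N = JAC / (V_insp / V_exp)` (normalized by the global lung-volume
   ratio), `JAC-NL = ln JAC-N` (0 = deforms like the lung as a whole,
   negative = relative shrinkage), and `JAC-NLC` = JAC-NL resampled into a
   common anatomical space via a mask-driven affine.
4. **Endpoints** — `Jac-mean = |mean(JAC-NLC)|` over the lung (one scalar
   per subject); marked-deformation areas `JAC-NLC ≤ −0.15`; the healthy
   deformation template (that segmentation applied to the control-group
   average map HAJ); and each subject's Dice overlap with the template,
   `Dice = 2·TP / (2·TP + FN + FP)`.
5. **Statistics** — group comparisons (t / Mann-Whitney U / chi-square),
   Spearman correlations of Jac-mean and Dice against pulmonary function
   (FVC%, FEV1%, TLC%, DLco%), the composite physiologic index
   `CPI = 91 − 0.65·DLco% − 0.53·FVC% + 0.34·FEV1%`, dyspnea grade (MRC),
   SGRQ quality-of-life scores, 6-minute walk distance and fibrosis extent;
   test-retest repeatability via ICC(2,1) and Bland-Altman 95% limits of
   agreement.

## Worked example

```python
from lungdeform.pipeline import PipelineConfig, analyze_cohort
from lungdeform.synthetic import make_cohort
from lungdeform import compare_groups, spearman

subjects, table = make_cohort(n_control=10, n_ipf=10, seed=7)
cfg = PipelineConfig(backend="oracle")       # ground-truth registration
cohort, artifacts = analyze_cohort(subjects, table, cfg)

ctrl = cohort[cohort.group == "control"]
ipf = cohort[cohort.group != "control"]
print(f"Jac-mean  control: {ctrl.jac_mean.mean():.3f} +- {ctrl.jac_mean.std():.3f}")
print(f"Jac-mean  IPF-like: {ipf.jac_mean.mean():.3f} +- {ipf.jac_mean.std():.3f}")
res = compare_groups(cohort.jac_mean, cohort.group, kind="mannwhitney")
print(f"Mann-Whitney U = {res.statistic:.0f}, p = {res.p_value:.2e}")
print(f"Dice vs healthy template  control: {ctrl.dice.mean():.3f}, IPF-like: {ipf.dice.mean():.3f}")
rho = spearman(cohort.jac_mean, cohort.dlco_pct)
print(f"Spearman Jac-mean vs DLco%: rho = {rho.statistic:.3f} (n = {rho.n[0]})")
```

prints

```
Jac-mean  control: 0.040 +- 0.005
Jac-mean  IPF-like: 0.009 +- 0.006
Mann-Whitney U = 100, p = 1.83e-04
Dice vs healthy template  control: 0.974, IPF-like: 0.634
Spearman Jac-mean vs DLco%: rho = 0.812 (n = 20)
```

The IPF-like group — whose peripheral/basal deformation the generator
attenuates — shows a lower Jac-mean (less deformation heterogeneity), a
lower Dice against the healthy-template motion pattern, and Jac-mean tracks
the generated diffusing capacity, as designed.

The same flow runs from the shell:

```sh
lungdeform simulate --n-control 6 --n-ipf 6 --seed 1 --out cohort/
lungdeform run --cohort cohort/ --out results/ --backend builtin
lungdeform stats --cohort results/derived/cohort_metrics.tsv --out stats/
```

`lungdeform run` writes per-subject metrics (`cohort_metrics.tsv`), the
healthy template and group maps (NIfTI), axis-projection images (PNG),
statistics tables (TSV) and a manifest with hashes of every output.

## Layout

| module | contents |
| --- | --- |
| `lungdeform.synthetic` | deformation model, phantom + cohort generator, ground-truth fields |
| `lungdeform.preprocess` | resampling, segmentation, dilation, volumes |
| `lungdeform.registration` | demons/external/oracle backends, mask affine, warping |
| `lungdeform.metrics` | JAC → JAC-N → JAC-NL → JAC-NLC, group maps, Jac-mean, template, Dice |
| `lungdeform.qc` | IoU, landmark distances, ICC(2,1), Bland-Altman |
| `lungdeform.stats` | CPI, group tests, Spearman, severity report |
| `lungdeform.pipeline` | cohort orchestration, disk layout, manifest |
| `lungdeform.cli` | `lungdeform` command |

See `docs/methods.md` for the model details, parameter choices and
limitations.
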