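# petimm

Synthetic-data re-implementation of an FDG PET/CT imaging-biomarker
analysis for colorectal cancer: adaptive-threshold tumor delineation,
first-order radiomics of the tumor SUV distribution, FDG uptake of the
reticuloendothelial system (bone marrow, liver, spleen), and the
statistics that relate those imaging features to the tumor immune
microenvironment and to recurrence-free survival (RFS).

It is written for imaging scientists who want to exercise, validate or
extend this analysis chain without access to clinical PET images: every
stage runs end-to-end on 3D PET phantoms and patient cohorts generated
with known ground truth.

## What it computes

**Tumor delineation.** The primary lesion is segmented with the adaptive
threshold

> T = 0.3 × (mean SUV of tumor voxels with SUV > 70 % of the tumor
> maximum) + (mean background SUV)

applied as a fixed-point iteration from a seed point, with the background
measured on an 8–16 mm shell around the current estimate.

**Ten first-order features** of the delineated tumor: maximum / mean /
median SUV, metabolic tumor volume (MTV, cm³), total lesion glycolysis
(TLG = MTV × mean SUV, g), coefficient of variation (CoV = σ/μ), and the
SUV-intensity-histogram kurtosis, skewness, entropy (−Σ p log₂ p, bits)
and uniformity (Σ p²) on a 64-bin discretization.

**Reference-organ uptake.** BM SUV (mean over six vertebral VOIs of the
voxels above 75 % of each VOI's maximum), liver SUV (3-cm spherical VOI),
spleen SUV (2-cm spherical VOI), and the ratios BLR = BM/liver,
SLR = spleen/liver.

**Cohort statistics.** Kruskal–Wallis tests of each feature across ordinal
immunohistochemistry grades (CD4/CD8/CD163 infiltration, IL-6/MMP-11
expression) with Dunn post-hoc comparisons, Mann–Whitney tests by tumor
grade, univariate Cox screening feeding a multivariate proportional-hazards
model (hazard ratios per conventional units, e.g. CoV per 0.10, SLR per
1.0), ROC/Youden cutoff selection, Kaplan–Meier curves with log-rank tests,
and a TNM-stage × imaging-risk recurrence table at the cutoffs CoV 0.25
and SLR 0.83.

See `docs/methods.md` for the generative models, conventions and
limitations.

## Worked example

```python
from petimm import (default_phantom_spec, generate_phantom,
                    delineate_tumor, extract_features)

spec = default_phantom_spec(seed=1)          # tumor + liver/spleen/vertebrae
vol, truth = generate_phantom(spec)
res = delineate_tumor(vol, spec.tumor_center_mm,
                      organ_masks=tuple(truth.organ_masks.values()))
print(f"threshold={res.threshold:.3f} SUV, iterations={res.iterations}, "
      f"MTV={res.mask.volume_cm3:.2f} cm3 (truth {truth.true_tumor_volume_cm3:.2f})")
print({k: round(v, 3) for k, v in extract_features(vol, res.mask).as_dict().items()})
```

prints

```
threshold=3.411 SUV, iterations=2, MTV=27.70 cm3 (truth 27.61)
{'max_suv': 9.763, 'mean_suv': 6.362, 'median_suv': 6.303, 'mtv_cm3': 27.705,
 'tlg_g': 176.262, 'cov_suv': 0.243, 'kurtosis': -0.972, 'skewness': 0.17,
 'entropy_bits': 5.838, 'uniformity': 0.019}
```

— the converged threshold is 0.3 × (core mean ≈ 8.0) + background ≈ 1.0;
the segmented MTV recovers the analytic 27.6 cm³ sphere to one voxel
layer; the measured CoV ≈ 0.24 matches the phantom's texture design.

The numbered drivers under `analysis/` run the full study: `01_simulate.py`
(30 phantoms + a 119-patient cohort), `02_segment_tumors.py`,
`03_extract_features.py`, `04_cohort_statistics.py`; their tables land
under `results/`. The same stages are available as a CLI
(`petimm simulate|segment|features|stats|all`).

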