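# Methods

`petimm` re-implements, as a tested pipeline over synthetic data, an FDG
PET/CT imaging-biomarker analysis for colorectal cancer: adaptive-threshold
delineation of the primary tumor, ten first-order imaging features,
reference-organ uptake of the reticuloendothelial system (bone marrow,
liver, spleen) with the BLR/SLR ratios, and the downstream statistics
linking imaging features to ordinal immunohistochemistry (IHC) grades and
recurrence-free survival (RFS). Because no clinical images or patient
tables are available, both substrates — 3D SUV volumes and patient cohorts
— are generated synthetically with known ground truth; every claim the test
suite makes is therefore a claim about the method's correctness and
calibration on data whose generating process is known, not about clinical
images.

## Phantoms

A phantom is a 3D SUV grid (default 64 × 64 × 56 voxels at
4.07 × 4.07 × 2.5 mm, the analysis voxel size) containing:

* a spherical tumor (default radius 18.75 mm ≙ 27.6 cm³, mean SUV 7,
  texture SD 1.68 → true coefficient of variation ≈ 0.24);
* a liver sphere (r = 24 mm, SUV 2.1), a spleen sphere (r = 17 mm, SUV 1.7)
  and six vertebral spheres (r = 9 mm, SUV 1.8), sized so the measurement
  VOIs (3 cm, 2 cm and 1.5 cm diameter respectively) fit inside them;
* a soft-tissue background (SUV 1.0) plus optional global Gaussian noise.

Intra-region texture is Gaussian white noise convolved with an isotropic
Gaussian kernel (correlation length 6 mm), rescaled to the requested
marginal SD — the simplest stationary field with a controllable CoV.
Because smoothing correlates voxels, the effective number of independent
samples in a region is roughly its volume divided by the correlation
volume; tests use that effective n in statistical tolerances. Negative
values arising from noise are clipped to zero (SUV is non-negative by
definition). No PET physics is simulated: no attenuation, scatter,
partial-volume PSF or reconstruction artifacts. Consequently phantom
edges are sharp, which makes threshold segmentation easier than on real
PET; the segmentation tests quantify discretization error only.

## Tumor delineation

The adaptive threshold is

```
T = 0.3 · mean{ SUV of tumor voxels strictly above 0.70 · max SUV } + mean background SUV
```

Both inequalities are strict (`> 70 %` for the core, `SUV > T` for
membership), matching the method's wording. The formula is
self-referential — the threshold defines the tumor that defines the core —
so `delineate_tumor` runs it as a fixed-point iteration:

1. initial estimate: the 26-connected component containing the seed at half
   the local maximum SUV within 12 mm of the seed (a standard PET seeding
   heuristic; insensitive on phantoms);
2. each iteration measures the background, applies the formula, and
   re-extracts the component anchored at the estimate's hottest voxel;
3. stop when the mask is unchanged, or at `max_iterations` (default 20;
   non-convergence sets a flag and warns rather than failing —
   `max_iterations=1` reproduces a one-shot application).

The background is not defined by the source method. Default here: a shell
8–16 mm from the current tumor surface (Euclidean distance in mm on voxel
centers), excluding any supplied organ masks; an explicit background mask
may be supplied instead. The shell geometry depends only on the mask, which
gives exact scale equivariance: scaling all SUVs by c > 0 scales the
converged threshold by c and leaves the converged mask unchanged (verified
by property test).

Resampling to the analysis grid is trilinear, edge-aligned with the source
field of view, and preserves constants and linear ramps to interpolation
round-off.

## First-order features

Six conventional features are computed on the raw masked voxels: maximum,
mean and median SUV; MTV (voxel count × voxel volume, cm³); TLG
(MTV × mean SUV, grams under the 1 g/cm³ density convention); and CoV
(population SD / mean; switchable to n−1). Four histogram features use a
fixed-bin-number discretization — 64 equal-width bins over the VOI's
[min, max], half-open intervals with the last bin closed (the documented
default of the LIFEx-family first-order convention; configurable):

* entropy = −Σ p·log₂p (bits, ≤ log₂ 64 = 6),
* uniformity = Σ p² (∈ [1/64, 1]),
* skewness = m₃/m₂^1.5 and kurtosis = m₄/m₂² − 3 (excess; switchable),
  computed on bin centers weighted by p.

A degenerate VOI (all values equal) puts all mass in bin 1; skewness and
kurtosis are returned as 0 with a warning. Because binning is relative to
the VOI's own range, entropy/uniformity/skewness/kurtosis are invariant
under positive affine intensity maps, while max/mean/median/TLG scale
linearly and MTV/CoV are invariant — all property-tested. Note that
threshold segmentation truncates the lower tail of the tumor distribution,
so the measured CoV of a segmented phantom is systematically below the
generator's marginal CoV; analyses compare like with like (measured vs
measured).

## Reference-organ uptake

Per vertebral VOI (default: 1.5 cm diameter sphere — unspecified in the
source protocol, chosen to fit a vertebral body at the analysis voxel
size), the measurement is the mean of voxels strictly above 75 % of the VOI
maximum; the core set can only be empty when the VOI maximum is 0, in which
case the mean over the whole VOI is returned with a warning. BM SUV is the
unweighted mean of the six vertebral measurements; exclusion of degenerate
vertebrae is the caller's responsibility (VOIs are inputs, not detected).
Liver and spleen SUV are plain means of 3 cm and 2 cm spherical VOIs;
sphere membership is by voxel-center inclusion, with no partial-volume
weighting, matching the voxel-counting MTV convention. BLR = BM/liver and
SLR = spleen/liver are scale-invariant by construction.

## Synthetic cohorts

Each of the 119 default records carries clinical covariates (age, sex,
location, CEA, size, grade, lymphovascular invasion, TNM stage, adjuvant
treatment) drawn with frequencies typical of a curative-surgery colorectal
series, five independent ordinal IHC grades, the imaging features, and a
censored RFS outcome.

* **Features** are log-normal (right-skewed, as PET medians/IQRs are), with
  the median multiplied by a per-(feature, marker) shift raised to the
  marker's grade. Default shifts encode the observed association
  directions: MTV and TLG fall with CD4 infiltration; entropy and BLR rise
  and CoV falls with CD163; uptake, volumetric features and SLR rise and
  uniformity falls with IL-6; CoV falls with MMP-11. BM and spleen SUV are
  derived as ratio × liver SUV so BLR/SLR identities hold exactly.
* **Survival** is exponential proportional hazards — the minimal model
  consistent with Cox assumptions — with default true log-hazards
  log 2.341 for stage III–IV, log 0.484 per 0.10 CoV and log 24.901 per
  1.0 SLR, and uniform censoring over 26.1–84.4 months (the follow-up
  range). The baseline rate (1.05 × 10⁻³ events/month at zero scaled
  covariates) is calibrated once so the generator reproduces the reference
  cohort's event fraction (~25 %) and 5-year RFS (~74 %).
* Markers are generated independently: no joint distribution between IHC
  markers is specified by the source material, so none is imposed; a
  coupling can be introduced through user-supplied grade probabilities per
  stratum if needed.

Everything is driven by `numpy.random.default_rng(seed)`: identical spec
and seed give bit-identical volumes and row-identical cohorts.

## Statistics

* Kruskal–Wallis (tie-corrected, via `scipy.stats.kruskal`) across grade
  groups; Dunn's rank-based post-hoc z tests with tie-corrected variance,
  unadjusted two-sided p by default (no adjustment is specified by the
  source analysis; Bonferroni and Holm are available by flag).
* Mann–Whitney U between binary groups; exact enumeration when both n ≤ 8
  and untied, tie-corrected normal approximation otherwise.
* Cox proportional hazards through `lifelines` (Efron tie handling — more
  accurate than Breslow at monthly granularity), Wald CIs. Covariates are
  divided by their reporting unit before fitting (CoV and uniformity per
  0.10, SLR/BLR per 1.0, MTV per 10 cm³, TLG per 10 g, CEA dichotomized at
  5 ng/ml), so hazard ratios are per printed unit. Univariate screening at
  α = 0.05 feeds the multivariate model; a p < 0.10 "borderline" tier is
  reported in outputs but never used for selection.
* ROC cutoffs maximize Youden's J over midpoints of sorted unique values,
  both dichotomization directions considered (low CoV adverse, high SLR
  adverse), ties broken toward the lower cutoff; the criterion is recorded
  in the result. The maximal J equals the two-sample Kolmogorov–Smirnov
  distance between the event and non-event feature distributions.
* Kaplan–Meier product-limit curves (Greenwood variance via `lifelines`),
  survival-at-60-months queries for 5-year RFS, and the log-rank test.
* The recurrence table stratifies by stage group {I–II, III–IV} × imaging
  group: both favorable (CoV > 0.25 and SLR < 0.83), mixed (exactly one
  unfavorable), both unfavorable (CoV ≤ 0.25 and SLR ≥ 0.83), reporting
  events/total and the percentage rate; empty cells report 0/0 with an
  undefined rate. The cutoffs 0.25 and 0.83 are treated as fixed inputs.
* Missing data: complete-case per analysis with logged exclusion counts.

## Problem sizes and numerical choices

The test suite runs phantom checks on ~50³ grids, oracle-equivalence
checks on 200 random small VOIs at 10⁻⁹ relative tolerance, and Cox
recovery on 20 replicates of n = 2000 cohorts (mean coefficient within 0.1
of truth, ≥ 90 % Wald CI coverage) — sizes chosen so the full suite runs in
well under a minute of phantom work while keeping Monte-Carlo noise far
below the asserted tolerances. The end-to-end smoke run uses 30 phantoms
and a 500-patient cohort. The acceptance script reports cohort-level
fractions at n = 20 000 and hazard-ratio recovery over 10 × n = 2000
replicates.

Fixed-point iteration caps at 20; all delineation runs observed on
phantoms converge in ≤ 5. Thresholds, cutoffs and bin boundaries use
strict/non-strict inequalities exactly as documented above; ties in
boolean masks cannot occur.

## Known limitations

* No PET physics: partial-volume blur is absent, so segmentation accuracy
  here is an upper bound on clinical performance, and the absolute values
  of histogram features on phantoms reflect the synthetic texture model,
  not tumor biology.
* Patient-level published statistics (feature medians by grade, fitted
  HRs/CIs on the clinical cohort, the 73.8 % 5-year RFS) depend on
  unreleased clinical data; the pipeline demonstrates recovery of known
  synthetic truth and exact reproduction of printed-count arithmetic, not
  of those patient-level values.
* IHC markers are sampled independently; real co-expression (e.g. CD163
  with IL-6) is not modelled.
* The exponential hazard is proportional by construction; the pipeline's
  Schoenfeld-style diagnostics are limited to what `lifelines` exposes.
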