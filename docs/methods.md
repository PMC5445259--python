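# Methods

## The problem

After a left-hemisphere stroke, damage to particular perisylvian sites —
the anterior supramarginal gyrus (SMG) and the pars opercularis of the
inferior frontal gyrus (pOp) — is associated with persistent phonological
impairments. `lesionmap` implements the ROI-guided lesion-deficit mapping
workflow that quantifies this association: binary lesion masks in a common
stereotactic space are compared against behavioural test scores, the
*critical damage threshold* of each region of interest is calibrated by
classification accuracy, the regions themselves are refined from lesion
overlap maps, and the result is validated on a held-out cohort.

## Data model

All images live on one `VolumeGrid` (shape + 4×4 RAS+ affine; 0-based
voxel indices). Grids that differ by more than 1e-5 in shape or affine are
an error — resampling is deliberately out of scope because every mask in
one analysis is assumed to be in the same standard space. mm→voxel
conversion applies the inverse affine and rounds half-away-from-zero per
axis, making the mapping deterministic and symmetric about voxel centres.

Behavioural scores are T-scores from an aphasia battery. Impairment on a
task is `T <= cutoff`, with the battery's published task cutoffs as
defaults (non-word reading 56, digit span 50, writing heard words 57,
visual word–picture 53, auditory word–picture 51, semantic associations
47). *Phonological impairment* is the conjunction of impaired non-word
reading and impaired digit span; *phonological severity* is the mean of
those two T-scores. Missing scores raise an explicit error and patients
with incomplete phonological scores are excluded listwise from
classification analyses — silently treating a missing score as
"unimpaired" would bias every 2×2 count.

## Damage quantification and threshold calibration

For a region R and lesion L, percent damage is `100·|L∩R|/|R|`. A region
counts as damaged when percent damage **≥** threshold (inclusive, matching
how above-threshold groups are reported with minima exactly at the
threshold). The threshold is calibrated over a grid (default 70/80/90/100 %)
by maximising the odds ratio of the damage-vs-impairment 2×2 table:

    OR = (a·d)/(b·c) = [PPV/(1−PPV)]·[NPV/(1−NPV)]

with a = damaged∧impaired, etc. When b or c is zero the odds ratio is
reported as *undefined* rather than infinite (an optional
Haldane–Anscombe +0.5 correction exists but is off by default); undefined
odds ratios rank below all defined ones during calibration, and ties break
to the higher threshold (the more conservative, smaller positive set).

## Region construction

* **Seed spheres** — 5 mm radius (~0.5 cm³) spheres centred on published
  stimulation/imaging coordinates, voxelized by voxel-centre distance ≤
  radius after snapping the centre to the nearest voxel centre.
* **Guided regions** — for a seed ROI, take the subgroup of patients with
  above-threshold seed damage *and* phonological impairment, build their
  lesion overlap map, keep voxels damaged in at least `ceil(0.85·m)` of
  the m subgroup members, and retain only 26-connected components touching
  the seed. The 85 % consistency default is a deliberate design choice:
  the stricter all-but-one rule (`m−1`, available as
  `cutoff="all_but_one"`) is not robust, because each subgroup lesion may
  legitimately miss a different fifth of the critical tissue (the damage
  threshold is below 100 %) and because a base rate of impairment
  unrelated to the seed (~15 %) contaminates the subgroup with lesions
  that erode the overlap core. In simulation the all-but-one core shrinks
  to a fraction of the true region while the 85 % rule recovers it with
  Dice ≈ 0.8–0.9. The cutoff is exposed as a count, a fraction, or
  "all_but_one"; the per-patient coverage of the final region is always
  reported alongside.
* **Unguided overlap region** — the overlap map of the impaired-only
  subgroup, with the overlap cutoff chosen by explicit search: for each
  candidate cutoff the candidate region's damage threshold is calibrated
  on the full cohort and the cutoff with the highest odds ratio wins
  (ties to the larger cutoff, i.e. the smaller region).
* **VLSM region** — voxels whose one-tailed p falls below 0.001
  (uncorrected) in the voxelwise analysis below.

## Voxel-based lesion-symptom mapping

Analysis is restricted to voxels lesioned in at least `ceil(0.20·n)`
patients. The default per-voxel statistic against a binary impairment
label is the Liebermeister quasi-exact test (the one-tailed Fisher p of
the table with the concordant cells incremented), with Fisher and Pearson
chi-square as alternatives; against a continuous score it is the pooled
two-sample t (lesioned vs intact at that voxel), one-tailed in the
deficit-with-lesion direction, with the equivalent point-biserial r
recoverable as r² = t²/(t²+df). Voxels where either group has fewer than
two patients are masked out. Family-wise error is controlled by
max-statistic permutation of the behavioural labels (default 1000
permutations, seeded and bit-reproducible); the voxel FWE p is the
proportion of permutation maxima at or above the observed statistic.

## Inferential toolbox

Group comparisons use: Pearson chi-square (df = 1, optional Yates
correction), Fisher's exact test (two-tailed by p-summation), McNemar's
test *without* continuity correction (the uncorrected formula reproduces
the published paired statistics exactly, e.g. χ² = 15.21 for discordant
pairs 18/1), the pooled-variance Student t with Cohen's d on the pooled
SD (the published dfs force the pooled rather than Welch form), the
Meng–Rosenthal–Rubin z for comparing two dependent correlations that
share a variable (the method is our choice; no specific method is named
for this comparison in the source analyses), a paired comparison of
predictive values (relative PPV/NPV with the asymptotic log-scale
variance obtained from the influence function of the paired empirical
estimator — equivalent to the standard paired-design relative-predictive-
value test), and the Bonferroni correction `min(1, m·p)`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Grid** — 64³ voxels at 2 mm (a toy standard space); the hemisphere
  mask is the left half minus a 2-voxel border.
* **Lesions** — grown by uniform random boundary accretion (Eden growth)
  from a seed voxel until a target volume is reached; every lesion is
  6-connected and contiguous. Target volumes follow a lognormal law with
  mean ≈ 80 cm³ and SD ≈ 80 cm³, truncated to [1.4, 464.7] cm³ — the
  scale and range of a real 1–5-years-post-stroke cohort. Seed voxels are
  drawn with a Gaussian bias (σ = 12 mm) toward a territory core,
  emulating the clustering of infarcts within one arterial territory;
  uniform seeding (σ = ∞) left almost no patients above the damage
  threshold and is not how real cohorts look.
* **Impairment rule** — a patient is *truly damaged* when any critical
  region is covered to at least its true threshold τ (default 80 %);
  impairment is Bernoulli with p = 0.85 given damage and p = 0.15
  otherwise (the incidences observed in the discovery sample).
* **Scores** — impaired patients draw non-word reading and digit span
  T-scores from N(47, 6) truncated to the impaired range of each task, so
  every simulated impaired patient genuinely meets the battery
  definition; spared patients draw from N(58, 7), redrawn until at least
  one phonological task is unimpaired. Remaining tasks use the same
  class-conditional normals untruncated.
* **Default critical region** — a 17 mm sphere (~20.4 cm³, the scale of a
  guided grey+white-matter region) at the territory core.

What the generator does *not* model: real vascular territory anatomy,
grey/white tissue contrast, multi-focal lesions, lesion-size–severity
coupling beyond the damage rule, and longitudinal recovery. Passing
recovery tests therefore show the estimators are consistent under the
assumed damage-conditional model, not that the anatomical conclusions of
any particular study are correct.

## Validation studies

* **Null calibration** (`validation.vlsm_type1_calibration`): one 50-patient
  lesion set; 500 replicates of scores drawn independently of the lesions;
  the fraction of analysed voxels with one-tailed p < 0.001 should equal
  0.001. Because voxels within a replicate share lesion patterns, the
  suprathreshold count is heavily over-dispersed relative to a binomial
  (observed replicate SD ~20× the binomial SD), so the check uses the
  replicate-level 95 % Monte-Carlo interval for the mean fraction — the
  statistically valid bound under spatial dependence.
* **Recovery study** (`validation.recovery_study`): 20 replicate cohorts
  at n = 150 under the default conditions; per cohort the calibrated
  threshold should equal the true τ = 80 % and the guided region should
  recover the true critical region with Dice > 0.7. Both hold jointly in
  ~90 % of cohorts.

## Numerical and engineering choices

* Rounding for display follows the published tables (whole percentages,
  odds ratios to one decimal); internal values are never rounded.
* The lesion-size matching rule restricts both groups to the shared
  volume window, then iteratively removes the patient farthest from the
  pooled mean until the pooled t-test is non-significant; only the window
  criterion is prescribed by the source procedure — the trim rule is ours.
* The outlier rule (scores > 3 SD below the group mean, computed once,
  non-iterative) cannot remove anything from very small groups: with n
  values a single point can be at most (n−1)/√n sample SDs from the mean,
  so exclusion only bites in realistically sized groups.
* Pipeline determinism: one global seed; per-stage randomness derived
  from it; reruns with the same config produce identical summaries.
* Problem sizes in tests and validation runs (64³ grid, cohorts of
  50–150, 500 replicates, 20 seeds) were chosen to exercise every code
  path at full statistical fidelity while keeping a complete run in the
  minutes range on one CPU.
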