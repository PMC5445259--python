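# lesionmap

ROI-guided lesion-deficit mapping for stroke cohorts: from binary lesion
masks (NIfTI, one standard space) and behavioural T-scores to calibrated
critical-damage thresholds, overlap-map-derived regions, voxel-based
lesion-symptom maps (VLSM), and classification-accuracy statistics
(PPV/NPV/sensitivity/specificity/odds ratio).

It is written for researchers who ask: *how consistently does damage to a
specific brain region cause a specific behavioural deficit?* Instead of
letting the lesion data alone pick the region (which biases results toward
tissue that strokes hit most often), the workflow starts from seed
coordinates established in independent experiments (e.g. TMS sites in
healthy volunteers), measures how well damage there predicts impairment,
and then refines the region from the lesion overlap of the patients it is
supposed to explain.

## The model

For each patient *i* and region *R*, percent damage is
`d_iR = 100·|L_i ∩ R|/|R|` where `L_i` is the binary lesion. A region is
*damaged* when `d_iR ≥ τ_R`; the critical threshold `τ_R` is calibrated
over a grid (70/80/90/100 %) by maximising the odds ratio of the 2×2
damage-by-impairment table,

    OR = (a·d)/(b·c) = [PPV/(1−PPV)] · [NPV/(1−NPV)],

where `a` counts damaged-and-impaired patients. Impairment itself is
defined behaviourally: T ≤ cutoff on *both* non-word reading and digit
span. Guided regions grow a seed sphere into the tissue damaged in at
least 85 % of the impaired, seed-damaged subgroup (26-connected to the
seed); the unguided alternative searches overlap cutoffs of the
impaired-only lesion overlap map by downstream odds ratio; VLSM tests
every well-covered voxel (Liebermeister/Fisher/chi-square or pooled t)
with max-statistic permutation FWE. A synthetic-cohort generator with
known ground truth (contiguous territory-clustered lesions, a
damage-conditional impairment rule, class-conditional T-scores) makes the
whole pipeline testable end to end.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import lesionmap as lm

# simulate a discovery cohort with known ground truth
cfg = lm.SimulationConfig(n_patients=150, seed=3)
records, lesions, truth = lm.simulate_cohort(cfg)

# seed ROI at the known site, calibrate its critical-damage threshold
grid = cfg.grid()
seed = lm.sphere_roi(cfg.critical_center_mm, 5.0, grid, name="seed")
impaired = {r.id: lm.phonological_impaired(r) for r in records}
pct = np.array([lm.percent_damage(lesions[r.id], seed) for r in records])
imp = np.array([impaired[r.id] for r in records])
thr, _ = lm.calibrate_threshold(pct, imp)

# grow the guided region from the seed-damaged, impaired subgroup,
# recalibrate its threshold, and compare with the generative truth
dmg = {r.id: bool(p >= thr) for r, p in zip(records, pct)}
region, coverage = lm.guided_region(seed, lesions, dmg, impaired)
gpct = np.array([lm.percent_damage(lesions[r.id], region) for r in records])
gthr, reports = lm.calibrate_threshold(gpct, imp)
print(lm.format_report_table(reports))
print(f"guided-region threshold: {gthr:.0f}%")
true_region = cfg.resolved_regions()[0].region
print(f"guided region: {region.volume_cm3:.1f} cm^3, "
      f"Dice vs truth = {lm.dice(region, true_region):.2f}")
```

Output:

```
Threshold %     n   PPV %   NPV %  Sens %  Spec %      OR
        100   150      60      64      11      96     2.6
         90   150      78      80      63      89    14.2
         80   150      77      88      81      85    23.6
         70   150      65      89      86      72    15.8
guided-region threshold: 80%
guided region: 21.5 cm^3, Dice vs truth = 0.90
```

Reading the table: at the calibrated 80 % threshold, 77 % of patients
with guided-region damage are impaired (PPV) and 88 % of patients without
damage are spared (NPV); the odds ratio multiplies the two predictive
odds and peaks at the true generative threshold of 80 %. The guided
region recovers the true ~20 cm³ critical region with Dice 0.90.

The same pipeline is scriptable from the shell:

```bash
lesionmap simulate-cohort --n 150 --seed 3 --out cohort/
lesionmap run-all --seed 3 --out run/
lesionmap stats --test chi2 --args '{"table": [10, 3, 10, 20]}'
```

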