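"""Simulation-based validation studies for the pipeline.

Two canned experiments quantify what the analysis can and cannot do on
cohorts with known ground truth:

* :func:`vlsm_type1_calibration` — under the global null (behavioural
  scores independent of the lesions) the fraction of analysed voxels below
  an uncorrected threshold should equal the nominal alpha;
* :func:`recovery_study` — on cohorts generated with the default
  damage-conditional impairment rule, the calibrated critical-damage
  threshold should recover the true tau and the overlap-guided region
  should recover the true critical region.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .damage import calibrate_threshold, percent_damage
from .regions import dice, guided_region, sphere_roi
from .simulate import SimulationConfig, simulate_cohort
from .vlsm import _stack, coverage_mask

__all__ = ["vlsm_type1_calibration", "recovery_study"]


def vlsm_type1_calibration(
    n_patients: int = 50,
    n_replicates: int = 500,
    alpha: float = 0.001,
    seed: int = 7,
) -> dict:
    """Null calibration of the voxelwise continuous test.

    One lesion set is simulated; each replicate draws scores independent of
    the lesions (equivalent to a random relabelling) and counts analysed
    voxels with one-tailed p < alpha.  Returns the pooled suprathreshold
    fraction, the replicate-level 95% Monte-Carlo interval for its mean,
    and whether alpha lies inside that interval.
    """
    cfg = SimulationConfig(n_patients=n_patients, seed=seed)
    _, lesions, _ = simulate_cohort(cfg)
    lesion_list = list(lesions.values())
    cov = coverage_mask(lesion_list, 0.20)
    L = _stack(lesion_list, cov).astype(float)
    n = n_patients
    n1 = L.sum(axis=0)
    n0 = n - n1
    usable = (n1 >= 2) & (n0 >= 2)
    df = n - 2
    n_voxels = int(usable.sum())

    rng = np.random.default_rng(seed + 1)
    fractions = np.empty(n_replicates)
    for i in range(n_replicates):
        sc = rng.standard_normal(n)
        s1 = sc @ L
        mean1 = s1 / n1
        mean0 = (sc.sum() - s1) / n0
        pooled = ((sc**2).sum() - n1 * mean1**2 - n0 * mean0**2) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean0 - mean1) / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
        p = sps.t.sf(t[usable], df)
        fractions[i] = (p < alpha).mean()

    mean_frac = float(fractions.mean())
    se = float(fractions.std(ddof=1) / np.sqrt(n_replicates))
    lo, hi = mean_frac - 1.96 * se, mean_frac + 1.96 * se
    return {
        "alpha": alpha,
        "n_voxels": n_voxels,
        "n_replicates": n_replicates,
        "fraction": mean_frac,
        "mc_interval": [lo, hi],
        "calibrated": bool(lo <= alpha <= hi),
    }


def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 1,
    n_patients: int = 150,
    dice_threshold: float = 0.7,
) -> dict:
    """Ground-truth recovery across replicate cohorts.

    For each seed: simulate a cohort under the default conditions (true
    threshold tau = 80 %, impairment incidence 0.85 damaged / 0.15 spared),
    calibrate the critical-damage threshold on the true region's damage
    percentages, and grow the guided region from a 5 mm seed sphere at the
    known site.  Success per seed = calibrated threshold equals tau AND
    Dice(recovered, true) > ``dice_threshold``.
    """
    results = []
    for i in range(n_seeds):
        cfg = SimulationConfig(n_patients=n_patients, seed=base_seed + i)
        records, lesions, truth = simulate_cohort(cfg)
        grid = cfg.grid()
        spec = cfg.resolved_regions()[0]
        true_region = spec.region
        impaired = {
            row["patient"]: bool(row["impaired"]) for row in truth["patients"]
        }
        pct_true = np.array(
            [row["damage_pct"][true_region.name] for row in truth["patients"]]
        )
        impaired_vec = np.array([impaired[row["patient"]] for row in truth["patients"]])
        try:
            thr, _ = calibrate_threshold(pct_true, impaired_vec)
        except Exception:
            thr = float("nan")

        seed_sphere = sphere_roi(
            cfg.critical_center_mm, 5.0, grid, name="seed", provenance="tms_sphere"
        )
        damage_flags = {
            pid: percent_damage(lesion, seed_sphere) >= spec.tau_pct
            for pid, lesion in lesions.items()
        }
        try:
            recovered, _ = guided_region(seed_sphere, lesions, damage_flags, impaired)
            d = dice(recovered, true_region)
        except Exception:
            d = 0.0
        results.append(
            {
                "seed": base_seed + i,
                "threshold": thr,
                "dice": float(d),
                "success": bool(thr == spec.tau_pct and d > dice_threshold),
            }
        )

    n_thr = sum(r["threshold"] == 80.0 for r in results)
    n_dice = sum(r["dice"] > dice_threshold for r in results)
    n_joint = sum(r["success"] for r in results)
    return {
        "n_seeds": n_seeds,
        "n_patients": n_patients,
        "true_tau_pct": 80.0,
        "threshold_recovered": n_thr,
        "dice_above_threshold": n_dice,
        "joint_successes": n_joint,
        "success_rate": n_joint / n_seeds,
        "mean_dice": float(np.mean([r["dice"] for r in results])),
        "per_seed": results,
    }
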