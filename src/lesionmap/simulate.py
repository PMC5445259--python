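"""Synthetic stroke-cohort generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes, with no
data dependencies: contiguous left-hemisphere lesions whose volumes follow
a truncated lognormal law (spanning roughly 1-465 cm^3 with mean ~80), a
damage-conditional impairment rule (a patient whose lesion covers at least
a critical fraction tau of a critical region is impaired with high
probability, ~0.85, and otherwise with low probability, ~0.15), and
class-conditional T-score distributions (impaired ~ N(47, 6), spared ~
N(58, 7)) truncated so that every simulated "impaired" patient actually
meets the battery's impairment definition.

Lesions are grown by uniform random boundary accretion from a seed voxel
inside the hemisphere mask: simple, contiguous (6-connected), and
spatially autocorrelated in the way that makes unguided overlap maps drift
toward the centre of the territory.  Seed voxels are drawn with a Gaussian
spatial bias toward a "territory core" (default: the critical-region
centre), emulating the clustering of real infarcts within one arterial
territory; a uniform-seed cohort is available by setting the territory
sigma to infinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .behavior import DEFAULT_CUTOFFS, ImpairmentCriteria, PatientRecord
from .imaging import BinaryVolume, VolumeGrid, toy_grid, volume_cm3
from .regions import Region, dice, sphere_roi

__all__ = [
    "CriticalRegionSpec",
    "SimulationConfig",
    "hemisphere_mask",
    "simulate_lesion",
    "simulate_cohort",
    "ground_truth_report",
]

_SIX_NEIGHBOURS = None  # flat-index offsets, grid-shape dependent


@dataclass
class CriticalRegionSpec:
    """One critical region with its true damage threshold and incidences."""

    region: Region
    tau_pct: float = 80.0
    p_impaired_given_damaged: float = 0.85
    p_impaired_given_spared: float = 0.15

    def __post_init__(self):
        if not (0.0 < self.tau_pct <= 100.0):
            raise ValueError("tau must be in (0, 100] %")
        for p in (self.p_impaired_given_damaged, self.p_impaired_given_spared):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate a 1-5-year post-stroke sample: n = 150 patients,
    lesion volumes lognormal with mean ~80 cm^3 and SD ~80 cm^3 truncated
    to [1.4, 464.7] cm^3, one ~20 cm^3 critical region with true threshold
    80 % and impairment incidences 0.85 (damaged) / 0.15 (spared).
    """

    n_patients: int = 150
    grid_n: int = 64
    voxel_mm: float = 2.0
    # lognormal parameters on the cm^3 scale: mean 80, SD 80 =>
    # sigma^2 = ln(1 + (80/80)^2), mu = ln(80) - sigma^2/2
    volume_mu: float = float(np.log(80.0) - np.log(2.0) / 2.0)
    volume_sigma: float = float(np.sqrt(np.log(2.0)))
    volume_min_cm3: float = 1.4
    volume_max_cm3: float = 464.7
    critical_regions: Optional[list[CriticalRegionSpec]] = None
    critical_center_mm: tuple[float, float, float] = (-32.0, -10.0, 8.0)
    critical_radius_mm: float = 17.0
    territory_center_mm: Optional[tuple[float, float, float]] = None  # default: critical centre
    territory_sigma_mm: float = 12.0
    impaired_score_mean: float = 47.0
    impaired_score_sd: float = 6.0
    spared_score_mean: float = 58.0
    spared_score_sd: float = 7.0
    months_post_stroke_mean: float = 32.4
    months_post_stroke_sd: float = 14.4
    months_post_stroke_range: tuple[float, float] = (12.0, 60.0)
    age_mean: float = 59.0
    age_sd: float = 12.7
    seed: int = 0

    def grid(self) -> VolumeGrid:
        return toy_grid(self.grid_n, self.voxel_mm)

    def default_critical_regions(self) -> list[CriticalRegionSpec]:
        """One spherical ~20 cm^3 critical region at the territory core.

        17 mm radius gives 4/3*pi*r^3 ~ 20.6 cm^3, the scale of an
        overlap-guided grey+white matter region.
        """
        grid = self.grid()
        region = sphere_roi(
            center_mm=self.critical_center_mm, radius_mm=self.critical_radius_mm,
            grid=grid, name="true_critical", provenance="custom",
        )
        return [CriticalRegionSpec(region=region)]

    def resolved_regions(self) -> list[CriticalRegionSpec]:
        return self.critical_regions or self.default_critical_regions()


def hemisphere_mask(grid: VolumeGrid, border: int = 2) -> BinaryVolume:
    """Left half of the grid minus a ``border``-voxel margin on every face.

    The margin guarantees lesion growth never reaches the array edge, so
    neighbourhood arithmetic needs no bounds checks.
    """
    nx, ny, nz = grid.shape
    data = np.zeros(grid.shape, dtype=bool)
    data[border : nx // 2, border : ny - border, border : nz - border] = True
    return BinaryVolume(grid, data)


def _flat_neighbour_offsets(shape) -> np.ndarray:
    nx, ny, nz = shape
    return np.array([ny * nz, -ny * nz, nz, -nz, 1, -1], dtype=np.int64)


def simulate_lesion(
    target_voxels: int,
    mask: BinaryVolume,
    rng: np.random.Generator,
    seed_index: int | None = None,
) -> BinaryVolume:
    """Grow one contiguous (6-connected) lesion of ``target_voxels`` voxels.

    Stochastic region growing: start at a random in-mask voxel and
    repeatedly annex a uniformly random boundary voxel that lies inside the
    mask, until the target count is reached.
    """
    mask_flat = mask.data.ravel()
    candidates = np.flatnonzero(mask_flat)
    if candidates.size == 0:
        raise ValueError("hemisphere mask is empty")
    if target_voxels < 1:
        raise ValueError("lesion must contain at least one voxel")
    if target_voxels > candidates.size:
        raise ValueError(
            f"target of {target_voxels} voxels exceeds mask size {candidates.size}"
        )
    offsets = _flat_neighbour_offsets(mask.grid.shape)

    if seed_index is None:
        seed_index = int(candidates[rng.integers(candidates.size)])
    lesion = np.zeros(mask_flat.size, dtype=bool)
    lesion[seed_index] = True
    count = 1
    frontier = [int(seed_index + o) for o in offsets if mask_flat[seed_index + o]]

    # uniform draws consumed in batches: one per annexation attempt
    batch = rng.random(4096)
    bi = 0
    while count < target_voxels:
        if not frontier:
            raise RuntimeError("lesion growth ran out of boundary voxels inside the mask")
        if bi == batch.size:
            batch = rng.random(4096)
            bi = 0
        j = int(batch[bi] * len(frontier))
        bi += 1
        frontier[j], frontier[-1] = frontier[-1], frontier[j]
        vox = frontier.pop()
        if lesion[vox]:
            continue
        lesion[vox] = True
        count += 1
        for o in offsets:
            nb = vox + o
            if mask_flat[nb] and not lesion[nb]:
                frontier.append(int(nb))
    return BinaryVolume(mask.grid, lesion.reshape(mask.grid.shape))


def _territory_seed_weights(
    config: SimulationConfig, grid: VolumeGrid, mask: BinaryVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian seed-placement weights over in-mask voxels.

    Infarct seeds cluster around the territory core with spatial scale
    ``territory_sigma_mm``; an infinite sigma reduces to uniform seeding.
    """
    candidates = np.flatnonzero(mask.data.ravel())
    if not np.isfinite(config.territory_sigma_mm):
        w = np.full(candidates.size, 1.0 / candidates.size)
        return w, candidates
    centre = np.asarray(
        config.territory_center_mm
        if config.territory_center_mm is not None
        else config.critical_center_mm,
        dtype=float,
    )
    ijk = np.array(np.unravel_index(candidates, grid.shape)).T
    mm = (np.asarray(grid.affine) @ np.c_[ijk, np.ones(len(ijk))].T).T[:, :3]
    d2 = ((mm - centre) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * config.territory_sigma_mm**2))
    return w / w.sum(), candidates


def _draw_volume_cm3(config: SimulationConfig, rng: np.random.Generator) -> float:
    # lognormal truncated to [min, max] by rejection (acceptance is high)
    for _ in range(10_000):
        v = float(np.exp(rng.normal(config.volume_mu, config.volume_sigma)))
        if config.volume_min_cm3 <= v <= config.volume_max_cm3:
            return v
    raise RuntimeError("volume law truncation rejected 10000 draws; check parameters")


def _truncnorm_below(mean, sd, upper, rng) -> float:
    alpha = (upper - mean) / sd
    if sps.norm.cdf(alpha) < 1e-6:
        raise ValueError(
            f"infeasible truncation: cutoff {upper} is {-alpha:.1f} SD above mean {mean}"
        )
    u = rng.uniform(0.0, sps.norm.cdf(alpha))
    return mean + sd * sps.norm.ppf(u)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], dict[str, BinaryVolume], dict]:
    """Simulate a full cohort: lesions, true damage states, and T-scores.

    Per patient: draw a lesion volume from the truncated lognormal, grow a
    contiguous lesion, mark the patient "truly damaged" if any critical
    region is covered to at least its tau, draw the impairment label from
    the damage-conditional Bernoulli, then draw T-scores from the
    class-conditional normals — the impaired class truncated so both
    phonological tasks fall in the impaired range, the spared class
    redrawn until at least one phonological task is unimpaired.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    mask = hemisphere_mask(grid)
    seed_weights, seed_candidates = _territory_seed_weights(config, grid, mask)
    specs = config.resolved_regions()
    for spec in specs:
        grid.require_compatible(spec.region.mask.grid, "critical region vs cohort grid")
    voxel_mm3 = grid.voxel_volume_mm3
    criteria = ImpairmentCriteria()
    cut_read = criteria.cutoff("nonword_reading")
    cut_digit = criteria.cutoff("digit_span")

    records: list[PatientRecord] = []
    lesions: dict[str, BinaryVolume] = {}
    truth_rows = []
    for i in range(config.n_patients):
        pid = f"sim{i:04d}"
        vol = _draw_volume_cm3(config, rng)
        target = max(1, int(round(vol * 1000.0 / voxel_mm3)))
        seed_index = int(seed_candidates[rng.choice(seed_candidates.size, p=seed_weights)])
        lesion = simulate_lesion(target, mask, rng, seed_index=seed_index)

        damage_pct = {}
        damaged = False
        p_imp = None
        for spec in specs:
            pct = 100.0 * int((lesion.data & spec.region.mask.data).sum()) / spec.region.n_voxels
            damage_pct[spec.region.name] = pct
            if pct >= spec.tau_pct:
                damaged = True
        # if several regions are damaged, the highest conditional wins
        if damaged:
            p_imp = max(
                s.p_impaired_given_damaged
                for s in specs
                if damage_pct[s.region.name] >= s.tau_pct
            )
        else:
            p_imp = max(s.p_impaired_given_spared for s in specs)
        impaired = bool(rng.random() < p_imp)

        tscores = {}
        if impaired:
            tscores["nonword_reading"] = _truncnorm_below(
                config.impaired_score_mean, config.impaired_score_sd, cut_read, rng
            )
            tscores["digit_span"] = _truncnorm_below(
                config.impaired_score_mean, config.impaired_score_sd, cut_digit, rng
            )
        else:
            for _ in range(10_000):
                read = rng.normal(config.spared_score_mean, config.spared_score_sd)
                digit = rng.normal(config.spared_score_mean, config.spared_score_sd)
                if read > cut_read or digit > cut_digit:
                    break
            else:
                raise RuntimeError("could not draw a spared score profile")
            tscores["nonword_reading"] = read
            tscores["digit_span"] = digit
        mean_other = (
            config.impaired_score_mean if impaired else config.spared_score_mean
        )
        sd_other = config.impaired_score_sd if impaired else config.spared_score_sd
        for task in ("nonword_repetition", "writing_heard_words", "visual_word_picture",
                     "auditory_word_picture", "semantic_associations"):
            tscores[task] = float(rng.normal(mean_other, sd_other))

        months = float(
            np.clip(
                rng.normal(config.months_post_stroke_mean, config.months_post_stroke_sd),
                *config.months_post_stroke_range,
            )
        )
        rec = PatientRecord(
            id=pid,
            lesion_size_cm3=volume_cm3(lesion),
            age_years=float(rng.normal(config.age_mean, config.age_sd)),
            months_post_stroke=months,
            sex="F" if rng.random() < 0.3 else "M",
            tscores=tscores,
        )
        records.append(rec)
        lesions[pid] = lesion
        truth_rows.append(
            {
                "patient": pid,
                "true_damaged": damaged,
                "impaired": impaired,
                "damage_pct": damage_pct,
                "volume_cm3": rec.lesion_size_cm3,
            }
        )

    truth = {
        "seed": config.seed,
        "regions": [
            {
                "name": s.region.name,
                "tau_pct": s.tau_pct,
                "p_impaired_given_damaged": s.p_impaired_given_damaged,
                "p_impaired_given_spared": s.p_impaired_given_spared,
                "volume_cm3": s.region.volume_cm3,
            }
            for s in specs
        ],
        "patients": truth_rows,
    }
    return records, lesions, truth


def ground_truth_report(
    truth: dict,
    recovered_threshold_pct: float | None = None,
    recovered_region: Region | None = None,
    true_region: Region | None = None,
    predicted_positive: Sequence[bool] | None = None,
) -> dict:
    """Score analysis outputs against the generator's ground truth."""
    report: dict = {"true_tau_pct": truth["regions"][0]["tau_pct"]}
    if recovered_threshold_pct is not None:
        report["recovered_threshold_pct"] = float(recovered_threshold_pct)
        report["threshold_recovered"] = (
            recovered_threshold_pct == truth["regions"][0]["tau_pct"]
        )
    if recovered_region is not None and true_region is not None:
        report["dice_vs_true_region"] = dice(recovered_region, true_region)
    if predicted_positive is not None:
        true_state = np.array([row["true_damaged"] for row in truth["patients"]])
        pred = np.asarray(predicted_positive, dtype=bool)
        report["damage_state_accuracy"] = float((pred == true_state).mean())
    return report
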