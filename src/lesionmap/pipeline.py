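"""End-to-end analysis pipeline with a serializable config.

Stages run in a fixed order — load or simulate the cohort, stratify,
build seed ROIs, compute damage profiles, calibrate critical-damage
thresholds, grow guided regions, search the unguided overlap map, run
VLSM, then evaluate everything on a held-out validation cohort with the
discovery-sample regions and thresholds frozen.  Every stage writes its
outputs (JSON/CSV/NIfTI) into the run directory, the effective config is
archived next to them, and a SHA-256 manifest records what was produced.
Discovery/validation separation is enforced by construction: the
validation stage receives only frozen Region objects and threshold
numbers, never the discovery data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import behavior, damage, regions, simulate, vlsm
from .imaging import read_mask, volume_cm3, write_mask

logger = logging.getLogger("lesionmap")

__all__ = ["PipelineConfig", "run_pipeline", "configure_logging"]


def configure_logging(level: str = "INFO", logfile: Optional[Path] = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable to/from YAML."""

    output_dir: str = "lesionmap_run"
    # real-data inputs (ignored when simulate=True)
    lesion_dir: Optional[str] = None
    score_table: Optional[str] = None
    column_map: dict = field(default_factory=dict)
    # simulation
    simulate: bool = True
    n_patients: int = 150
    n_validation: int = 100
    # analysis options
    seed_coords_mm: dict = field(default_factory=dict)  # name -> [x, y, z]
    seed_radius_mm: float = 5.0
    threshold_grid: list = field(default_factory=lambda: [70.0, 80.0, 90.0, 100.0])
    cutoff_overrides: dict = field(default_factory=dict)  # task -> T cutoff
    vlsm_test: str = "liebermeister"
    vlsm_alpha: float = 0.001
    vlsm_min_coverage: float = 0.20
    n_permutations: int = 0  # 0 disables permutation FWE
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    def criteria(self) -> behavior.ImpairmentCriteria:
        crit = behavior.ImpairmentCriteria()
        crit.cutoffs.update(self.cutoff_overrides)
        return crit


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(config: PipelineConfig):
    """Returns (records, lesions dict, truth-or-None) for discovery and
    validation cohorts."""
    if config.simulate:
        sim = simulate.SimulationConfig(n_patients=config.n_patients, seed=config.seed)
        records, lesions, truth = simulate.simulate_cohort(sim)
        val_sim = dataclasses.replace(
            sim,
            n_patients=config.n_validation,
            seed=config.seed + 1,
            months_post_stroke_mean=121.0,
            months_post_stroke_sd=72.0,
            months_post_stroke_range=(61.0, 432.0),
        )
        v_records, v_lesions, v_truth = simulate.simulate_cohort(val_sim)
        return (records, lesions, truth), (v_records, v_lesions, v_truth), sim
    if not config.lesion_dir or not config.score_table:
        raise ValueError("need lesion_dir and score_table when simulate is false")
    records = behavior.read_score_table(config.score_table, config.column_map)
    lesions = {}
    lesion_dir = Path(config.lesion_dir)
    for rec in records:
        hits = sorted(lesion_dir.glob(f"{rec.id}.nii*"))
        if not hits:
            raise FileNotFoundError(f"no lesion mask for patient {rec.id} in {lesion_dir}")
        lesions[rec.id] = read_mask(hits[0])
        if np.isnan(rec.lesion_size_cm3):
            rec.lesion_size_cm3 = volume_cm3(lesions[rec.id])
    strata = behavior.stratify_samples(records)
    disc = strata["sample_1"]
    val = strata["sample_2"]
    return (
        (disc, {r.id: lesions[r.id] for r in disc}, None),
        (val, {r.id: lesions[r.id] for r in val}, None),
        None,
    )


def _evaluate(records, lesions, named_regions, thresholds, criteria):
    """Frozen-region evaluation: damage profile + classification per region
    set, using only patients with complete phonological scores."""
    usable = [
        r for r in records
        if r.has_score("nonword_reading") and r.has_score("digit_span")
    ]
    impaired = np.array([behavior.phonological_impaired(r, criteria) for r in usable])
    profile = damage.DamageProfile.from_lesions(
        {r.id: lesions[r.id] for r in usable}, named_regions
    )
    ids = [r.id for r in usable]
    out = {}
    for name in named_regions:
        positives = damage.binarize_damage(profile.percent(name, ids), thresholds[name])
        out[name] = damage.classification_report(
            positives, impaired, thresholds[name]
        ).to_dict()
    if len(named_regions) > 1:
        positives = damage.region_set_positive(
            profile, list(named_regions), thresholds, ids
        )
        out["any_region"] = damage.classification_report(positives, impaired).to_dict()
    return out, profile


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    configure_logging(config.log_level, run_dir / "run.log")
    config.to_yaml(run_dir / "config.yaml")
    manifest: dict[str, str] = {}
    criteria = config.criteria()

    logger.info("stage 1: load cohort")
    (records, lesions, truth), (v_records, v_lesions, v_truth), sim = _load_cohort(config)
    grid = next(iter(lesions.values())).grid
    logger.info("discovery n=%d, validation n=%d", len(records), len(v_records))

    logger.info("stage 2: seed ROIs")
    seed_coords = dict(config.seed_coords_mm)
    if not seed_coords:
        if sim is not None:
            seed_coords = {"seed": list(sim.critical_center_mm)}
        else:
            seed_coords = {
                name: list(coord)
                for name, coord in regions.DEFAULT_SEEDS_MM.items()
                if name in ("tms_smg", "tms_pop")
            }
    seed_rois = {
        name: regions.sphere_roi(coord, config.seed_radius_mm, grid, name=name,
                                 provenance="tms_sphere")
        for name, coord in seed_coords.items()
    }

    logger.info("stage 3: damage profile for seed ROIs")
    impaired = {r.id: behavior.phonological_impaired(r, criteria) for r in records}
    impaired_vec = np.array([impaired[r.id] for r in records])
    profile = damage.DamageProfile.from_lesions(lesions, seed_rois)
    profile.to_csv(run_dir / "damage_seed_rois.csv")
    manifest["damage_seed_rois.csv"] = _sha256(run_dir / "damage_seed_rois.csv")

    logger.info("stage 4: calibrate seed-ROI thresholds")
    ids = [r.id for r in records]
    calibration: dict[str, dict] = {}
    thresholds: dict[str, float] = {}
    for name in seed_rois:
        thr, reports = damage.calibrate_threshold(
            profile.percent(name, ids), impaired_vec, config.threshold_grid
        )
        thresholds[name] = thr
        calibration[name] = {
            "threshold_pct": thr,
            "by_threshold": {t: rep.to_dict() for t, rep in reports.items()},
        }
        (run_dir / f"calibration_{name}.txt").write_text(
            damage.format_report_table(reports) + "\n"
        )

    logger.info("stage 5: guided regions")
    guided: dict[str, regions.Region] = {}
    guided_thresholds: dict[str, float] = {}
    for name, roi in seed_rois.items():
        flags = {
            pid: bool(p >= thresholds[name])
            for pid, p in zip(ids, profile.percent(name, ids))
        }
        try:
            reg, coverage = regions.guided_region(roi, lesions, flags, impaired,
                                                  name=f"{name}_guided")
        except ValueError as exc:
            logger.warning("guided region for %s failed: %s", name, exc)
            continue
        guided[reg.name] = reg
        pct = np.array([damage.percent_damage(lesions[p], reg) for p in ids])
        thr, _ = damage.calibrate_threshold(pct, impaired_vec, config.threshold_grid)
        guided_thresholds[reg.name] = thr
        regions.write_region(reg, run_dir / f"{reg.name}.nii.gz")

    logger.info("stage 6: unguided overlap-map search")
    impaired_lesions = {pid: lesions[pid] for pid in ids if impaired[pid]}
    cutoff, unguided, unguided_rep, trace = regions.unguided_region_search(
        impaired_lesions, lesions, impaired, config.threshold_grid
    )
    regions.write_region(unguided, run_dir / "unguided_lom.nii.gz")

    logger.info("stage 7: VLSM")
    lesion_list = [lesions[pid] for pid in ids]
    cov = vlsm.coverage_mask(lesion_list, config.vlsm_min_coverage)
    statmap = vlsm.vlsm_binary(lesion_list, impaired_vec, cov, test=config.vlsm_test)
    vlsm_region = vlsm.threshold_statmap(statmap, config.vlsm_alpha)
    write_mask(vlsm_region.mask, run_dir / "vlsm_region.nii.gz")
    vlsm_out = {
        "n_analysed_voxels": statmap.n_analysed,
        "alpha": config.vlsm_alpha,
        "region_volume_cm3": vlsm_region.volume_cm3,
    }
    if config.n_permutations:
        fwe, _, _ = vlsm.permutation_fwe(
            lesion_list, impaired_vec, cov,
            n_perm=config.n_permutations, seed=config.seed, test=config.vlsm_test,
        )
        vlsm_out["n_fwe_significant"] = int(((fwe < 0.05) & cov.data).sum())

    logger.info("stage 8: frozen evaluation on validation cohort")
    eval_regions: dict[str, object] = dict(guided)
    eval_thresholds = dict(guided_thresholds)
    if unguided.n_voxels:
        eval_regions["unguided_lom"] = unguided
        eval_thresholds["unguided_lom"] = unguided.meta["calibrated_threshold_pct"]
    validation, _ = _evaluate(v_records, v_lesions, eval_regions, eval_thresholds, criteria)

    logger.info("stage 9: summary")
    summary = {
        "n_discovery": len(records),
        "n_validation": len(v_records),
        "seed_roi_calibration": calibration,
        "guided_regions": {
            name: {"volume_cm3": reg.volume_cm3, "threshold_pct": guided_thresholds[name],
                   **reg.meta}
            for name, reg in guided.items()
        },
        "unguided_search": {
            "cutoff": cutoff,
            "volume_cm3": unguided.volume_cm3,
            "report": unguided_rep.to_dict(),
        },
        "vlsm": vlsm_out,
        "validation": validation,
    }
    if truth is not None:
        true_region = simulate.SimulationConfig(seed=config.seed).resolved_regions()[0].region
        first_guided = next(iter(guided.values()), None)
        summary["ground_truth"] = simulate.ground_truth_report(
            truth,
            recovered_threshold_pct=next(iter(thresholds.values()), None),
            recovered_region=first_guided,
            true_region=true_region,
        )
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest["summary.json"] = _sha256(run_dir / "summary.json")
    for p in sorted(run_dir.iterdir()):
        if p.name not in manifest and p.is_file() and p.name != "manifest.json":
            manifest[p.name] = _sha256(p)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", run_dir)
    return run_dir
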