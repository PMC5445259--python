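"""Regions of interest: coordinate-seeded spheres, lesion overlap maps,
overlap-guided region growth and the unguided overlap-cutoff search.

Three families of regions are supported:

* *seed spheres* — small (default 5 mm radius, ~0.5 cm^3) spheres centred
  on stereotactic mm coordinates from stimulation or functional-imaging
  studies of healthy participants;
* *guided regions* — the grey/white matter around a seed that is most
  consistently damaged in the patients who have both above-threshold
  damage to the seed and the behavioural impairment (built from a lesion
  overlap map of that subgroup, restricted to 26-connected components that
  touch the seed);
* *unguided / data-driven regions* — thresholded overlap maps of the
  impaired-only subgroup, with the overlap cutoff chosen by downstream
  classification accuracy (odds ratio).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .damage import (
    ClassificationReport,
    calibrate_threshold,
    classification_report,
    percent_damage,
)
from .imaging import BinaryVolume, VolumeGrid, mm_to_voxel, volume_cm3, voxel_to_mm, write_mask

__all__ = [
    "Region",
    "OverlapMap",
    "DEFAULT_SEEDS_MM",
    "sphere_roi",
    "euclidean_distance",
    "overlap_map",
    "region_from_overlap",
    "guided_region",
    "unguided_region_search",
    "dice",
    "write_region",
]

#: seed coordinates (stereotactic mm) for the two phonological sites, as
#: localized by stimulation studies (tms_*) and reported by
#: functional-imaging studies (fmri_*); *_mean are across-study means.
DEFAULT_SEEDS_MM: dict[str, tuple[float, float, float]] = {
    "tms_smg": (-52.0, -34.0, 30.0),
    "tms_pop": (-52.0, 16.0, 8.0),
    "fmri_smg_mean": (-51.0, -32.0, 42.0),
    "fmri_pop_mean": (-52.0, 6.0, 20.0),
    "fmri_smg_1": (-57.0, -21.0, 39.0),
    "fmri_smg_2": (-42.0, -40.0, 46.0),
    "fmri_smg_3": (-54.0, -36.0, 40.0),
    "fmri_pop_1": (-58.0, 5.0, 13.0),
    "fmri_pop_2": (-50.0, 6.0, 24.0),
    "fmri_pop_3": (-57.0, 9.0, 24.0),
    "fmri_pop_4": (-41.0, 3.0, 20.0),
}

PROVENANCES = (
    "tms_sphere",
    "fmri_sphere",
    "tms_guided",
    "fmri_guided",
    "unguided_lom",
    "vlsm",
    "custom",
)

#: 26-connectivity structuring element for component labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Region:
    name: str
    mask: BinaryVolume
    provenance: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def volume_cm3(self) -> float:
        return volume_cm3(self.mask)

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels


@dataclass
class OverlapMap:
    """Voxelwise count of how many cohort lesions include each voxel."""

    grid: VolumeGrid
    counts: np.ndarray
    n_patients: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if counts.min() < 0 or counts.max() > self.n_patients:
            raise ValueError("overlap counts must lie in [0, n_patients]")
        self.counts = counts.astype(np.int32, copy=False)

    @property
    def max_overlap(self) -> int:
        return int(self.counts.max())


def euclidean_distance(p_mm, q_mm) -> float:
    """L2 distance in mm between two stereotactic coordinates."""
    return float(np.linalg.norm(np.asarray(p_mm, float) - np.asarray(q_mm, float)))


def sphere_roi(
    center_mm,
    radius_mm: float = 5.0,
    grid: VolumeGrid | None = None,
    name: str = "sphere",
    provenance: str = "custom",
) -> Region:
    """Spherical ROI: voxels whose centre lies within ``radius_mm`` of the
    seed (the seed is snapped to the nearest voxel centre first)."""
    if grid is None:
        raise ValueError("a VolumeGrid is required to voxelize the sphere")
    center_vox = mm_to_voxel(grid, center_mm)  # raises if outside the grid
    center_snapped = voxel_to_mm(grid, center_vox)

    # bound the search box by the radius in voxel units
    inv = np.linalg.inv(np.asarray(grid.affine))
    vox_sizes = np.linalg.norm(np.asarray(grid.affine)[:3, :3], axis=0)
    half = np.ceil(radius_mm / vox_sizes).astype(int) + 1
    lo = np.maximum(np.array(center_vox) - half, 0)
    hi = np.minimum(np.array(center_vox) + half + 1, grid.shape)

    data = np.zeros(grid.shape, dtype=bool)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    mm = (np.asarray(grid.affine) @ vox.T).T[:, :3]
    inside = np.linalg.norm(mm - center_snapped, axis=1) <= radius_mm
    data[vox[inside, 0], vox[inside, 1], vox[inside, 2]] = True
    if not data.any():
        raise ValueError("sphere does not cover any voxel of the grid")
    return Region(
        name,
        BinaryVolume(grid, data),
        provenance,
        meta={"center_mm": list(map(float, center_mm)), "radius_mm": float(radius_mm)},
    )


def overlap_map(lesions: Sequence[BinaryVolume], ids: Sequence[str] | None = None) -> OverlapMap:
    """Sum binary lesions voxelwise into an integer overlap map."""
    if not lesions:
        raise ValueError("need at least one lesion")
    grid = lesions[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for i, lesion in enumerate(lesions):
        try:
            grid.require_compatible(lesion.grid)
        except Exception as exc:
            who = ids[i] if ids else f"index {i}"
            raise type(exc)(f"lesion {who}: {exc}") from exc
        counts += lesion.data
    return OverlapMap(grid, counts, len(lesions))


def region_from_overlap(
    lom: OverlapMap, cutoff: int, name: str = "overlap_region", provenance: str = "unguided_lom"
) -> Region:
    """Voxels lesioned in at least ``cutoff`` of the contributing patients."""
    if not (1 <= cutoff <= lom.n_patients):
        raise ValueError(f"cutoff must be in [1, {lom.n_patients}], got {cutoff}")
    data = lom.counts >= cutoff
    region = Region(
        name,
        BinaryVolume(lom.grid, data),
        provenance,
        meta={"cutoff": int(cutoff), "n_patients": lom.n_patients},
    )
    if not data.any():
        region.meta["empty"] = True
    return region


def _components_touching(mask: np.ndarray, seed: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    touching = np.unique(labels[seed & (labels > 0)])
    return np.isin(labels, touching[touching > 0])


#: default overlap-consistency fraction for guided regions: keep tissue
#: damaged in at least this share of the defining subgroup
GUIDED_CONSISTENCY = 0.85


def guided_region(
    seed: Region,
    lesions: Mapping[str, BinaryVolume],
    damage_flags: Mapping[str, bool],
    impaired_flags: Mapping[str, bool],
    cutoff: int | float | str | None = None,
    name: str | None = None,
    provenance: str = "tms_guided",
) -> tuple[Region, dict[str, float]]:
    """Grow a seed ROI into the surrounding tissue most consistently damaged
    in the impaired, seed-damaged subgroup.

    The subgroup is every patient with ``damage_flags`` and
    ``impaired_flags`` both true.  Its lesion overlap map is thresholded at
    a cutoff and restricted to 26-connected components intersecting the
    seed mask.  The cutoff policy is configurable:

    * ``None`` (default) — tissue damaged in at least 85 % of the subgroup
      (``ceil(0.85 * m)``), robust to the occasional subgroup member whose
      impairment is unrelated to the seed;
    * a float in (0, 1] — a different consistency fraction;
    * an int — an explicit overlap count;
    * ``"all_but_one"`` — the strictest tolerant rule, ``m - 1``.

    Returns the region plus, for each subgroup patient, the percent of the
    region their lesion covers.
    """
    if seed.n_voxels == 0:
        raise ValueError("seed region is empty")
    subgroup = [pid for pid in lesions if damage_flags.get(pid) and impaired_flags.get(pid)]
    if not subgroup:
        raise ValueError("no patient has both above-threshold seed damage and impairment")
    m = len(subgroup)
    if m < 2:
        warnings.warn(
            f"guided region for seed {seed.name!r} is based on a single patient; "
            "the result is that patient's lesion component", stacklevel=2
        )
    lom = overlap_map([lesions[pid] for pid in subgroup], subgroup)
    if cutoff is None:
        cutoff = GUIDED_CONSISTENCY
    if cutoff == "all_but_one":
        cutoff = max(1, m - 1)
    elif isinstance(cutoff, float) and 0.0 < cutoff <= 1.0:
        cutoff = max(1, int(np.ceil(cutoff * m)))
    if not (isinstance(cutoff, (int, np.integer)) and 1 <= cutoff <= m):
        raise ValueError(f"cutoff must be in [1, {m}] for a subgroup of {m}")
    core = lom.counts >= cutoff
    kept = _components_touching(core, seed.mask.data)
    if not kept.any():
        raise ValueError(
            f"no overlap component at cutoff {cutoff} touches the seed {seed.name!r}"
        )
    region = Region(
        name or f"{seed.name}_guided",
        BinaryVolume(lom.grid, kept),
        provenance,
        meta={
            "seed": seed.name,
            "subgroup_ids": subgroup,
            "subgroup_size": m,
            "cutoff": int(cutoff),
        },
    )
    coverage = {pid: percent_damage(lesions[pid], region) for pid in subgroup}
    return region, coverage


def unguided_region_search(
    subgroup_lesions: Mapping[str, BinaryVolume],
    eval_lesions: Mapping[str, BinaryVolume],
    eval_impaired: Mapping[str, bool],
    threshold_grid: Sequence[float] = (70.0, 80.0, 90.0, 100.0),
    name: str = "unguided_lom",
) -> tuple[int, Region, ClassificationReport, dict]:
    """Search overlap cutoffs of the impaired-only overlap map.

    For each candidate cutoff from the subgroup size down to 1, the
    thresholded overlap region has its critical-damage threshold calibrated
    on the evaluation cohort; the cutoff/threshold pair with the highest
    odds ratio wins (ties to the larger cutoff, i.e. the smaller region).
    """
    if not subgroup_lesions:
        raise ValueError("subgroup is empty")
    ids = list(subgroup_lesions)
    lom = overlap_map([subgroup_lesions[pid] for pid in ids], ids)
    eval_ids = list(eval_lesions)
    impaired = np.array([bool(eval_impaired[pid]) for pid in eval_ids])

    # flatten eval lesions once for fast region coverage
    stack = np.stack([eval_lesions[pid].data.ravel() for pid in eval_ids])
    flat_counts = lom.counts.ravel()

    best: Optional[tuple[int, float, ClassificationReport]] = None
    best_or = -np.inf
    trace = {}
    for cutoff in range(lom.n_patients, 0, -1):
        region_vec = flat_counts >= cutoff
        size = int(region_vec.sum())
        if size == 0:
            continue
        pct = 100.0 * (stack[:, region_vec].sum(axis=1)) / size
        try:
            thr, reports = calibrate_threshold(pct, impaired, threshold_grid)
        except Exception:
            continue
        rep = reports[thr]
        oratio = rep.odds_ratio
        trace[cutoff] = {"threshold": thr, "odds_ratio": oratio, "n_voxels": size}
        if oratio is not None and oratio > best_or:
            best_or = oratio
            best = (cutoff, thr, rep)
    if best is None:
        raise RuntimeError("no overlap cutoff produced a defined odds ratio")
    cutoff, thr, rep = best
    region = region_from_overlap(lom, cutoff, name=name, provenance="unguided_lom")
    region.meta.update({"calibrated_threshold_pct": thr, "odds_ratio": best_or})
    return cutoff, region, rep, trace


def dice(a: BinaryVolume | Region, b: BinaryVolume | Region) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    ma = a.mask if isinstance(a, Region) else a
    mb = b.mask if isinstance(b, Region) else b
    ma.grid.require_compatible(mb.grid)
    na, nb = ma.n_voxels, mb.n_voxels
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma.data & mb.data).sum()) / (na + nb)


def write_region(region: Region, path: str | Path) -> Path:
    """Write the region mask as NIfTI plus a JSON provenance sidecar."""
    path = Path(path)
    write_mask(region.mask, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii / .nii.gz
    sidecar = Path(str(sidecar) + ".json")
    payload = {
        "name": region.name,
        "provenance": region.provenance,
        "volume_cm3": region.volume_cm3,
        "n_voxels": region.n_voxels,
        **region.meta,
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return path
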