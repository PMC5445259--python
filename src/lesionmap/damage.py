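"""Regional damage quantification and critical-damage threshold calibration.

For each patient and region of interest the pipeline computes *percent
damage* — the share of the region's voxels covered by the patient's lesion.
A region is then called "damaged" when percent damage meets or exceeds a
threshold, and the threshold itself is calibrated by classification
accuracy: over a grid of candidate thresholds (70/80/90/100 % by default)
the one whose 2x2 table of damage-vs-impairment has the highest odds ratio
wins.  Classification accuracy is summarised as PPV, NPV, sensitivity,
specificity and the odds ratio; the odds ratio is left *undefined* (not
infinite) when a zero off-diagonal cell makes it so.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import BinaryVolume

__all__ = [
    "ContingencyTable2x2",
    "ClassificationReport",
    "DamageProfile",
    "CalibrationError",
    "percent_damage",
    "binarize_damage",
    "region_set_positive",
    "classification_report",
    "calibrate_threshold",
    "reconstruct_table",
    "format_report_table",
    "DEFAULT_THRESHOLD_GRID",
]

DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (70.0, 80.0, 90.0, 100.0)


def _mask_of(region) -> BinaryVolume:
    # accepts a BinaryVolume or anything with a .mask attribute (a Region)
    return region.mask if hasattr(region, "mask") else region


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts at one damage threshold.

    a = damaged & impaired, b = damaged & spared,
    c = spared-region & impaired, d = spared-region & spared.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self, haldane: bool = False) -> Optional[float]:
        """(a*d)/(b*c); None when a zero b or c cell leaves it undefined.

        ``haldane=True`` applies the Haldane-Anscombe +0.5 correction to all
        cells instead of returning None.
        """
        if haldane:
            return (self.a + 0.5) * (self.d + 0.5) / ((self.b + 0.5) * (self.c + 0.5))
        if self.b == 0 or self.c == 0:
            return None
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class ClassificationReport:
    threshold_pct: float
    table: ContingencyTable2x2

    @property
    def ppv(self) -> float:
        t = self.table
        return 100.0 * t.a / (t.a + t.b) if t.a + t.b else float("nan")

    @property
    def npv(self) -> float:
        t = self.table
        return 100.0 * t.d / (t.c + t.d) if t.c + t.d else float("nan")

    @property
    def sensitivity(self) -> float:
        t = self.table
        return 100.0 * t.a / (t.a + t.c) if t.a + t.c else float("nan")

    @property
    def specificity(self) -> float:
        t = self.table
        return 100.0 * t.d / (t.b + t.d) if t.b + t.d else float("nan")

    @property
    def odds_ratio(self) -> Optional[float]:
        return self.table.odds_ratio()

    def to_dict(self) -> dict:
        return {
            "threshold_pct": self.threshold_pct,
            "n": self.table.n,
            "table": {"a": self.table.a, "b": self.table.b, "c": self.table.c, "d": self.table.d},
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "odds_ratio": self.odds_ratio,
        }


@dataclass
class DamageProfile:
    """Tidy per-patient, per-region percent-damage table."""

    rows: pd.DataFrame  # columns: patient, region, percent_damage
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        required = {"patient", "region", "percent_damage"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"DamageProfile rows missing columns: {sorted(missing)}")
        pct = self.rows["percent_damage"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("percent_damage must lie in [0, 100]")

    @classmethod
    def from_lesions(
        cls,
        lesions: Mapping[str, BinaryVolume],
        regions: Mapping[str, object],
    ) -> "DamageProfile":
        rows = [
            {
                "patient": pid,
                "region": rname,
                "percent_damage": percent_damage(lesion, region),
            }
            for pid, lesion in lesions.items()
            for rname, region in regions.items()
        ]
        return cls(pd.DataFrame(rows))

    def percent(self, region: str, patients: Sequence[str] | None = None) -> np.ndarray:
        sub = self.rows[self.rows["region"] == region].set_index("patient")["percent_damage"]
        if patients is None:
            return sub.to_numpy(dtype=float)
        return sub.loc[list(patients)].to_numpy(dtype=float)

    def patients(self, region: str) -> list[str]:
        return self.rows.loc[self.rows["region"] == region, "patient"].tolist()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DamageProfile":
        return cls(pd.read_csv(path))


def percent_damage(lesion: BinaryVolume, region) -> float:
    """100 x |lesion AND region| / |region|; the region must be non-empty."""
    mask = _mask_of(region)
    lesion.grid.require_compatible(mask.grid, "lesion vs region")
    denom = int(mask.data.sum())
    if denom == 0:
        raise ValueError("cannot compute percent damage for an empty region")
    return 100.0 * int((lesion.data & mask.data).sum()) / denom


def binarize_damage(percent: Sequence[float] | np.ndarray, threshold_pct: float) -> np.ndarray:
    """Damage call per patient: percent damage >= threshold (inclusive)."""
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError(f"threshold must be in (0, 100] %, got {threshold_pct}")
    return np.asarray(percent, dtype=float) >= threshold_pct


def region_set_positive(
    profile: DamageProfile,
    regions: Sequence[str],
    thresholds: Mapping[str, float],
    patients: Sequence[str] | None = None,
) -> np.ndarray:
    """Positive iff damage to *any* listed region meets its threshold."""
    if patients is None:
        patients = profile.patients(regions[0])
    positive = np.zeros(len(patients), dtype=bool)
    for region in regions:
        if region not in thresholds:
            raise KeyError(f"no calibrated threshold for region {region!r}")
        positive |= binarize_damage(profile.percent(region, patients), thresholds[region])
    return positive


def classification_report(
    positives: Sequence[bool], impaired: Sequence[bool], threshold_pct: float = float("nan")
) -> ClassificationReport:
    """Build the 2x2 table and derived accuracy metrics."""
    positives = np.asarray(positives, dtype=bool)
    impaired = np.asarray(impaired, dtype=bool)
    if positives.shape != impaired.shape or positives.size == 0:
        raise ValueError("positives and impaired must be equal-length, non-empty")
    a = int(np.sum(positives & impaired))
    b = int(np.sum(positives & ~impaired))
    c = int(np.sum(~positives & impaired))
    d = int(np.sum(~positives & ~impaired))
    return ClassificationReport(threshold_pct, ContingencyTable2x2(a, b, c, d))


class CalibrationError(RuntimeError):
    def __init__(self, message: str, reports: dict | None = None):
        super().__init__(message)
        self.reports = reports or {}


def calibrate_threshold(
    percent: Sequence[float] | np.ndarray,
    impaired: Sequence[bool],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> tuple[float, dict[float, ClassificationReport]]:
    """Pick the damage threshold with the highest odds ratio.

    Every candidate threshold in ``grid`` is evaluated; undefined odds
    ratios rank below all defined ones, and ties go to the higher
    threshold (the smaller positive set).  All candidate reports are
    returned for a full accuracy-by-threshold table.
    """
    percent = np.asarray(percent, dtype=float)
    impaired = np.asarray(impaired, dtype=bool)
    if int(impaired.sum()) < 2 or int((~impaired).sum()) < 2:
        raise ValueError("need at least 2 patients in each impairment class")
    reports: dict[float, ClassificationReport] = {}
    best_thr: Optional[float] = None
    best_or = -math.inf
    for thr in grid:
        rep = classification_report(binarize_damage(percent, thr), impaired, thr)
        reports[float(thr)] = rep
        oratio = rep.odds_ratio
        if oratio is None:
            continue
        if oratio > best_or or (oratio == best_or and thr > best_thr):
            best_or, best_thr = oratio, float(thr)
    if best_thr is None:
        raise CalibrationError("no candidate threshold yields a defined odds ratio", reports)
    return best_thr, reports


def reconstruct_table(
    n: int,
    ppv_pct: float,
    npv_pct: float,
    sensitivity_pct: float,
    specificity_pct: float,
    n_impaired: int | None = None,
) -> ContingencyTable2x2:
    """Recover the integer 2x2 table behind whole-percent accuracy figures.

    Enumerates all tables with total ``n`` (optionally fixing the impaired
    margin) whose PPV/NPV/sensitivity/specificity round (half away from
    zero) to the printed whole percentages; requires the solution to be
    unique.
    """

    def rounds_to(x: float, target: float) -> bool:
        return math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1) == target

    hits = []
    for k in ([n_impaired] if n_impaired is not None else range(1, n)):
        for a in range(0, k + 1):
            c = k - a
            for b in range(0, n - k + 1):
                d = n - k - b
                if a + b == 0 or c + d == 0 or b + d == 0:
                    continue
                if not rounds_to(100.0 * a / (a + b), ppv_pct):
                    continue
                if not rounds_to(100.0 * d / (c + d), npv_pct):
                    continue
                if not rounds_to(100.0 * a / k, sensitivity_pct):
                    continue
                if not rounds_to(100.0 * d / (b + d), specificity_pct):
                    continue
                hits.append(ContingencyTable2x2(a, b, c, d))
    if not hits:
        raise ValueError("no integer 2x2 table matches the printed percentages")
    if len(hits) > 1:
        raise ValueError(f"ambiguous reconstruction: {len(hits)} tables match")
    return hits[0]


def format_report_table(reports: Mapping[float, ClassificationReport]) -> str:
    """Plain-text accuracy table: Threshold, n, PPV, NPV, Sens, Spec, OR."""
    lines = [
        f"{'Threshold %':>11}  {'n':>4}  {'PPV %':>6}  {'NPV %':>6}  "
        f"{'Sens %':>6}  {'Spec %':>6}  {'OR':>6}"
    ]
    for thr in sorted(reports, reverse=True):
        rep = reports[thr]
        oratio = rep.odds_ratio
        or_str = f"{oratio:.1f}" if oratio is not None else "-"
        lines.append(
            f"{thr:>11.0f}  {rep.table.n:>4d}  {rep.ppv:>6.0f}  {rep.npv:>6.0f}  "
            f"{rep.sensitivity:>6.0f}  {rep.specificity:>6.0f}  {or_str:>6}"
        )
    return "\n".join(lines)
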