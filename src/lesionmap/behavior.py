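"""Behavioural data model: T-scores, impairment criteria, cohort handling.

Impairment on each language-battery task is defined by an inclusive T-score
cutoff (score <= cutoff is impaired); "phonological impairment" is the
conjunction of impaired non-word reading and impaired digit span, and
phonological severity is the mean of those two T-scores.  Missing scores
always propagate as an explicit :class:`MissingScoreError` — a patient with
an absent score is never silently classified as unimpaired.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TASKS",
    "DEFAULT_CUTOFFS",
    "PatientRecord",
    "ImpairmentCriteria",
    "MissingScoreError",
    "is_task_impaired",
    "phonological_impaired",
    "phonological_severity",
    "tms_composite",
    "exclude_low_outliers",
    "stratify_samples",
    "match_lesion_size",
    "MatchingError",
    "read_score_table",
    "write_score_table",
]

TASKS = (
    "nonword_reading",
    "digit_span",
    "nonword_repetition",
    "writing_heard_words",
    "visual_word_picture",
    "auditory_word_picture",
    "semantic_associations",
)

#: impaired range is T <= cutoff, per task
DEFAULT_CUTOFFS: dict[str, float] = {
    "nonword_reading": 56.0,
    "digit_span": 50.0,
    "writing_heard_words": 57.0,
    "visual_word_picture": 53.0,
    "auditory_word_picture": 51.0,
    "semantic_associations": 47.0,
}


class MissingScoreError(KeyError):
    """A task score required for classification is absent."""


@dataclass
class PatientRecord:
    id: str
    lesion_size_cm3: float = float("nan")
    age_years: float = float("nan")
    months_post_stroke: float = float("nan")
    sex: str = ""
    tscores: dict[str, float] = field(default_factory=dict)
    tms_accuracy_pct: Optional[float] = None
    tms_median_rt_ms: Optional[float] = None
    lesion: object = None  # BinaryVolume or key into a lesion store

    def score(self, task: str) -> float:
        value = self.tscores.get(task)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingScoreError(f"patient {self.id}: missing score for task {task!r}")
        return float(value)

    def has_score(self, task: str) -> bool:
        value = self.tscores.get(task)
        return value is not None and not (isinstance(value, float) and math.isnan(value))


@dataclass
class ImpairmentCriteria:
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    phonological_tasks: tuple[str, str] = ("nonword_reading", "digit_span")

    def cutoff(self, task: str) -> float:
        if task not in self.cutoffs:
            raise KeyError(f"no impairment cutoff defined for task {task!r}")
        return self.cutoffs[task]


def is_task_impaired(
    record: PatientRecord, task: str, criteria: ImpairmentCriteria | None = None
) -> bool:
    """True iff the patient's T-score on ``task`` is <= the task cutoff."""
    criteria = criteria or ImpairmentCriteria()
    return record.score(task) <= criteria.cutoff(task)


def phonological_impaired(
    record: PatientRecord, criteria: ImpairmentCriteria | None = None
) -> bool:
    """Impaired on *both* phonological tasks (non-word reading and digit span)."""
    criteria = criteria or ImpairmentCriteria()
    t1, t2 = criteria.phonological_tasks
    return is_task_impaired(record, t1, criteria) and is_task_impaired(record, t2, criteria)


def phonological_severity(
    record: PatientRecord, criteria: ImpairmentCriteria | None = None
) -> float:
    """Mean T-score over the two phonological tasks (lower = more severe)."""
    criteria = criteria or ImpairmentCriteria()
    t1, t2 = criteria.phonological_tasks
    return (record.score(t1) + record.score(t2)) / 2.0


def tms_composite(accuracy_pct: float, median_rt_ms: float) -> float:
    """Speed-accuracy composite: percent accuracy / median correct RT x 1000."""
    if median_rt_ms <= 0:
        raise ValueError(f"median RT must be positive, got {median_rt_ms}")
    if not (0.0 <= accuracy_pct <= 100.0):
        raise ValueError(f"accuracy must be in [0, 100] %, got {accuracy_pct}")
    return accuracy_pct / median_rt_ms * 1000.0


def exclude_low_outliers(scores: Sequence[float], k: float = 3.0) -> list[int]:
    """Indices of scores that are *not* more than ``k`` SD below the mean.

    Mean and sample SD (ddof=1) are computed once over all scores;
    the rule is non-iterative.  An SD of zero excludes nothing.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores to define outliers")
    mean = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0:
        return list(range(scores.size))
    keep = scores >= mean - k * sd
    return [int(i) for i in np.flatnonzero(keep)]


def stratify_samples(
    cohort: Sequence[PatientRecord],
    min_size_cm3: float = 1.0,
    split_months: tuple[float, float] = (12.0, 60.0),
) -> dict[str, list[PatientRecord]]:
    """Split a cohort into the 1-5-year and >5-year post-stroke samples.

    Patients with lesions <= ``min_size_cm3`` are excluded first; the
    remainder split on months post-stroke: [12, 60] months (sample_1) versus
    >60 months (sample_2).  Patients under 12 months are excluded too.
    """
    lo, hi = split_months
    out: dict[str, list[PatientRecord]] = {"sample_1": [], "sample_2": [], "excluded": []}
    for rec in cohort:
        months = rec.months_post_stroke
        if math.isnan(months) or math.isnan(rec.lesion_size_cm3):
            raise ValueError(f"patient {rec.id}: months_post_stroke / lesion size required")
        if months < 0:
            raise ValueError(f"patient {rec.id}: negative time post-stroke")
        if rec.lesion_size_cm3 <= min_size_cm3 or months < lo:
            out["excluded"].append(rec)
        elif months <= hi:
            out["sample_1"].append(rec)
        else:
            out["sample_2"].append(rec)
    return out


class MatchingError(RuntimeError):
    """Lesion-size matching between two groups is impossible."""


def match_lesion_size(
    group_a: Sequence[PatientRecord],
    group_b: Sequence[PatientRecord],
    alpha: float = 0.05,
) -> tuple[list[PatientRecord], list[PatientRecord], dict]:
    """Match two groups on lesion volume.

    First restrict both groups to the shared volume window
    [max(min_a, min_b), min(max_a, max_b)].  Then, while a pooled two-sample
    t-test on mean lesion volume rejects at ``alpha``, drop the single
    patient whose volume lies farthest from the pooled mean (ties resolved
    by dropping from the larger group).
    """
    if not group_a or not group_b:
        raise MatchingError("both groups must be non-empty")
    vols_a = [r.lesion_size_cm3 for r in group_a]
    vols_b = [r.lesion_size_cm3 for r in group_b]
    lo = max(min(vols_a), min(vols_b))
    hi = min(max(vols_a), max(vols_b))
    if lo > hi:
        raise MatchingError(
            f"lesion-volume ranges do not overlap: [{min(vols_a)}, {max(vols_a)}] "
            f"vs [{min(vols_b)}, {max(vols_b)}]"
        )
    a = [r for r in group_a if lo <= r.lesion_size_cm3 <= hi]
    b = [r for r in group_b if lo <= r.lesion_size_cm3 <= hi]

    removed: list[str] = []
    while True:
        if len(a) < 2 or len(b) < 2:
            raise MatchingError("matching exhausted a group before reaching p >= alpha")
        va = np.array([r.lesion_size_cm3 for r in a])
        vb = np.array([r.lesion_size_cm3 for r in b])
        t, p = sps.ttest_ind(va, vb, equal_var=True)
        if p >= alpha or np.isnan(p):
            break
        pooled_mean = np.concatenate([va, vb]).mean()
        dev_a = np.abs(va - pooled_mean)
        dev_b = np.abs(vb - pooled_mean)
        worst_a, worst_b = dev_a.max(), dev_b.max()
        if worst_a > worst_b or (worst_a == worst_b and len(a) >= len(b)):
            idx = int(dev_a.argmax())
            removed.append(a[idx].id)
            del a[idx]
        else:
            idx = int(dev_b.argmax())
            removed.append(b[idx].id)
            del b[idx]

    report = {
        "window_cm3": [float(lo), float(hi)],
        "n_a": len(a),
        "n_b": len(b),
        "removed_ids": removed,
        "t": float(t),
        "p": float(p),
        "mean_a": float(np.mean([r.lesion_size_cm3 for r in a])),
        "mean_b": float(np.mean([r.lesion_size_cm3 for r in b])),
    }
    return a, b, report


# ---------------------------------------------------------------------------
# tabular I/O


_DEFAULT_COLUMNS = {
    "id": "id",
    "lesion_size_cm3": "lesion_size_cm3",
    "age_years": "age_years",
    "months_post_stroke": "months_post_stroke",
    "sex": "sex",
    "tms_accuracy_pct": "tms_accuracy_pct",
    "tms_median_rt_ms": "tms_median_rt_ms",
}


def read_score_table(
    path: str | Path, column_map: Mapping[str, str] | None = None, sep: str | None = None
) -> list[PatientRecord]:
    """Read a delimited score table (header row required) into records.

    ``column_map`` maps canonical field/task names to the file's column
    names; unmapped canonical names fall back to identity.  The delimiter is
    sniffed from the extension (.tsv -> tab) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    cmap = dict(_DEFAULT_COLUMNS)
    cmap.update({t: t for t in TASKS})
    if column_map:
        cmap.update(column_map)

    records = []
    for _, row in df.iterrows():
        def get(name, default=float("nan")):
            col = cmap.get(name, name)
            if col in df.columns and not pd.isna(row[col]):
                return row[col]
            return default

        tscores = {}
        for task in TASKS:
            col = cmap[task]
            if col in df.columns and not pd.isna(row[col]):
                tscores[task] = float(row[col])
        acc = get("tms_accuracy_pct", None)
        rt = get("tms_median_rt_ms", None)
        records.append(
            PatientRecord(
                id=str(get("id", "")),
                lesion_size_cm3=float(get("lesion_size_cm3")),
                age_years=float(get("age_years")),
                months_post_stroke=float(get("months_post_stroke")),
                sex=str(get("sex", "")),
                tscores=tscores,
                tms_accuracy_pct=None if acc is None else float(acc),
                tms_median_rt_ms=None if rt is None else float(rt),
            )
        )
    return records


def write_score_table(records: Iterable[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "lesion_size_cm3": r.lesion_size_cm3,
            "age_years": r.age_years,
            "months_post_stroke": r.months_post_stroke,
            "sex": r.sex,
            "tms_accuracy_pct": r.tms_accuracy_pct,
            "tms_median_rt_ms": r.tms_median_rt_ms,
        }
        for task in TASKS:
            row[task] = r.tscores.get(task)
        rows.append(row)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path
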