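"""Voxel-based lesion-symptom mapping (VLSM).

Each voxel with enough lesion coverage is tested for an association
between lesion status and behaviour: a 2x2 test against a binary
impairment label (Liebermeister quasi-exact by default; Fisher and Pearson
chi-square as alternatives), or a pooled two-sample t-test against a
continuous score (lesioned vs intact patients at that voxel).  All tests
are one-tailed in the deficit-with-lesion direction by default.  Family-
wise error is controlled by max-statistic permutation of the behavioural
labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .imaging import BinaryVolume, VolumeGrid
from .regions import Region

__all__ = [
    "StatMap",
    "coverage_mask",
    "vlsm_binary",
    "vlsm_continuous",
    "threshold_statmap",
    "permutation_fwe",
    "BINARY_TESTS",
]

BINARY_TESTS = ("liebermeister", "fisher", "chi2")

_P_FLOOR = 1e-300  # avoid inf z-scores for vanishing p


@dataclass
class StatMap:
    grid: VolumeGrid
    statistic: np.ndarray
    p_one_tailed: np.ndarray
    analysed_mask: BinaryVolume
    test_name: str

    def __post_init__(self):
        inside = self.analysed_mask.data
        p = self.p_one_tailed[inside]
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("p-values outside [0, 1]")

    @property
    def n_analysed(self) -> int:
        return self.analysed_mask.n_voxels


def _stack(lesions: Sequence[BinaryVolume], mask: BinaryVolume) -> np.ndarray:
    grid = mask.grid
    flat_mask = mask.data.ravel()
    rows = []
    for i, lesion in enumerate(lesions):
        grid.require_compatible(lesion.grid, f"lesion index {i}")
        rows.append(lesion.data.ravel()[flat_mask])
    return np.stack(rows)  # n_patients x n_voxels


def coverage_mask(lesions: Sequence[BinaryVolume], min_prop: float = 0.20) -> BinaryVolume:
    """Voxels damaged in at least ceil(min_prop * n) patients (never fewer
    than one)."""
    if not lesions:
        raise ValueError("need at least one lesion")
    if not 0.0 <= min_prop <= 1.0:
        raise ValueError("min_prop must be in [0, 1]")
    n = len(lesions)
    cutoff = max(1, math.ceil(min_prop * n))
    grid = lesions[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for i, lesion in enumerate(lesions):
        grid.require_compatible(lesion.grid, f"lesion index {i}")
        counts += lesion.data
    return BinaryVolume(grid, counts >= cutoff)


def _binary_p_table(n: int, k: int, test: str) -> np.ndarray:
    """One-tailed p for every (a, m) cell of an n-patient, k-impaired 2x2.

    Indexed [a, m] where m is the lesioned count at the voxel and a the
    lesioned-and-impaired count; the alternative is "lesions are more
    frequent in the impaired group".
    """
    a = np.arange(n + 1)[:, None]
    m = np.arange(n + 1)[None, :]
    if test == "fisher":
        # P(A >= a) under hypergeom(n, k, m)
        return sps.hypergeom.sf(a - 1, n, k, m)
    if test == "liebermeister":
        # quasi-exact: Fisher one-tailed p of the table with a+1 and d+1
        return sps.hypergeom.sf(a, n + 2, k + 1, m + 1)
    if test == "chi2":
        b = m - a
        c = k - a
        d = n - k - b
        with np.errstate(divide="ignore", invalid="ignore"):
            margins = (a + c).astype(float) * (b + d) * m * (n - m)
            chi2 = n * (a * d - b * c) ** 2.0 / margins
            chi2 = np.where(margins > 0, chi2, 0.0)
            sign = np.sign(a * d - b * c)
        p_two = sps.chi2.sf(chi2, 1)
        return np.where(sign > 0, p_two / 2.0, 1.0 - p_two / 2.0)
    raise ValueError(f"unknown binary test {test!r} (choose from {BINARY_TESTS})")


def vlsm_binary(
    lesions: Sequence[BinaryVolume],
    impaired: Sequence[bool],
    mask: BinaryVolume | None = None,
    test: str = "liebermeister",
    two_tailed: bool = False,
) -> StatMap:
    """Per-voxel 2x2 lesion-by-impairment test over the analysed mask."""
    impaired = np.asarray(impaired, dtype=bool)
    n = len(lesions)
    if impaired.size != n:
        raise ValueError("one impairment label per lesion required")
    k = int(impaired.sum())
    if k < 2 or n - k < 2:
        raise ValueError("need at least 2 patients per impairment class")
    if mask is None:
        mask = coverage_mask(lesions)
    if mask.n_voxels == 0:
        raise ValueError("analysed mask is empty")
    L = _stack(lesions, mask)
    m = L.sum(axis=0)
    a = impaired.astype(np.int32) @ L
    table = _binary_p_table(n, k, test)
    p = table[a, m]
    if two_tailed:
        p = np.minimum(1.0, 2.0 * np.minimum(p, 1.0 - p))
    z = sps.norm.isf(np.maximum(p, _P_FLOOR))
    return _fill_statmap(mask, z, p, f"vlsm-{test}" + ("-2t" if two_tailed else ""))


def vlsm_continuous(
    lesions: Sequence[BinaryVolume],
    scores: Sequence[float],
    mask: BinaryVolume | None = None,
    min_group: int = 2,
) -> StatMap:
    """Per-voxel pooled t-test of scores, lesioned vs intact patients.

    Positive statistics mean lower scores in the lesioned group (the
    deficit direction); one-tailed p accordingly.  Voxels where either
    group falls below ``min_group`` are removed from the analysed mask.
    The point-biserial r is recoverable as r^2 = t^2 / (t^2 + df).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(lesions)
    if scores.size != n:
        raise ValueError("one score per lesion required")
    if n < 4:
        raise ValueError("need at least 4 patients")
    if np.isnan(scores).any():
        raise ValueError("scores must be complete (no NaN)")
    if mask is None:
        mask = coverage_mask(lesions)
    L = _stack(lesions, mask).astype(float)
    n1 = L.sum(axis=0)                      # lesioned count per voxel
    n0 = n - n1
    usable = (n1 >= min_group) & (n0 >= min_group)
    s1 = scores @ L
    q1 = (scores**2) @ L
    s_tot, q_tot = scores.sum(), (scores**2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / n1
        mean0 = (s_tot - s1) / n0
        ss = (q_tot - n1 * mean1**2 - n0 * mean0**2)
        df = n - 2
        pooled = ss / df
        t = (mean0 - mean1) / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    t = np.where(usable & np.isfinite(t), t, 0.0)
    p = sps.t.sf(t, df)
    p = np.where(usable, p, 1.0)

    new_mask_flat = mask.data.ravel().copy()
    idx = np.flatnonzero(new_mask_flat)
    new_mask_flat[idx[~usable]] = False
    new_mask = BinaryVolume(mask.grid, new_mask_flat.reshape(mask.grid.shape))
    return _fill_statmap(mask, t, p, "vlsm-pooled-t", analysed=new_mask)


def _fill_statmap(
    mask: BinaryVolume, stat_vec: np.ndarray, p_vec: np.ndarray, name: str,
    analysed: BinaryVolume | None = None,
) -> StatMap:
    grid = mask.grid
    stat = np.zeros(grid.shape)
    p = np.ones(grid.shape)
    stat[mask.data] = stat_vec
    p[mask.data] = p_vec
    return StatMap(grid, stat, p, analysed or mask, name)


def threshold_statmap(
    statmap: StatMap, alpha: float = 0.001, name: str = "vlsm_region"
) -> Region:
    """Suprathreshold region: analysed voxels with p < alpha."""
    data = (statmap.p_one_tailed < alpha) & statmap.analysed_mask.data
    region = Region(
        name,
        BinaryVolume(statmap.grid, data),
        provenance="vlsm",
        meta={"alpha": float(alpha), "test": statmap.test_name},
    )
    if not data.any():
        region.meta["empty"] = True
    return region


def permutation_fwe(
    lesions: Sequence[BinaryVolume],
    outcome: Sequence,
    mask: BinaryVolume | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    test: str = "liebermeister",
) -> tuple[np.ndarray, StatMap, np.ndarray]:
    """Max-statistic permutation FWE correction.

    Permutes the behavioural labels ``n_perm`` times, records the maximum
    voxel statistic of each permutation, and assigns each voxel the FWE p
    equal to the proportion of permutation maxima at or above its observed
    statistic.  Binary outcomes use the chosen 2x2 test; continuous
    outcomes the pooled t.  Bit-reproducible for a fixed seed.

    Returns (fwe_p inside-mask vector as a 3-D array, observed StatMap,
    permutation maxima).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    outcome = np.asarray(outcome)
    binary = outcome.dtype == bool or set(np.unique(outcome)).issubset({0, 1})
    rng = np.random.default_rng(seed)
    n = len(lesions)
    if mask is None:
        mask = coverage_mask(lesions)

    if math.lgamma(n + 1) < math.log(n_perm):
        import warnings

        warnings.warn(
            f"only {math.factorial(n)} distinct permutations exist for n={n}; "
            f"FWE resolution is limited", stacklevel=2
        )

    L = _stack(lesions, mask)
    m = L.sum(axis=0)
    if binary:
        labels = outcome.astype(bool)
        k = int(labels.sum())
        table = _binary_p_table(n, k, test)
        ztab = sps.norm.isf(np.maximum(table, _P_FLOOR))

        def stat_of(lbl):
            a = lbl.astype(np.int32) @ L
            return ztab[a, m]

        observed_map = vlsm_binary(lesions, labels, mask, test=test)
        obs = observed_map.statistic[mask.data]
        maxima = np.empty(n_perm)
        for i in range(n_perm):
            maxima[i] = stat_of(rng.permutation(labels)).max()
    else:
        scores = outcome.astype(float)
        observed_map = vlsm_continuous(lesions, scores, mask)
        obs = observed_map.statistic[mask.data]
        Lf = L.astype(float)
        n1 = m.astype(float)
        n0 = n - n1
        usable = (n1 >= 2) & (n0 >= 2)
        df = n - 2

        def t_of(sc):
            s1 = sc @ Lf
            q_tot = (sc**2).sum()
            mean1 = s1 / n1
            mean0 = (sc.sum() - s1) / n0
            pooled = (q_tot - n1 * mean1**2 - n0 * mean0**2) / df
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (mean0 - mean1) / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
            return np.where(usable & np.isfinite(t), t, 0.0)

        maxima = np.empty(n_perm)
        for i in range(n_perm):
            maxima[i] = t_of(rng.permutation(scores)).max()

    sorted_max = np.sort(maxima)
    # proportion of permutation maxima >= observed statistic, per voxel
    fwe_vec = 1.0 - np.searchsorted(sorted_max, obs, side="left") / n_perm
    fwe = np.ones(mask.grid.shape)
    fwe[mask.data] = fwe_vec
    return fwe, observed_map, maxima
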