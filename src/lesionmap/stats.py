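"""Inferential toolbox for cohort comparisons.

Implements the tests used to compare lesion groups: Pearson chi-square and
Fisher's exact test on 2x2 incidence tables, McNemar's test for paired
proportions, the pooled two-sample t-test with Cohen's d for severity,
the Meng-Rosenthal-Rubin z for comparing dependent (overlapping)
correlations, a paired comparison of predictive values (relative PPV/NPV
with an asymptotic log-scale variance that respects the pairing), and the
Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .damage import ContingencyTable2x2

__all__ = [
    "TestResult",
    "chi2_2x2",
    "fisher_exact",
    "mcnemar",
    "ttest_pooled",
    "compare_dependent_correlations",
    "compare_paired_predictive_values",
    "bonferroni",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: Optional[float] = None
    effect_size: Optional[float] = None
    tails: int = 2

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect_size": self.effect_size,
            "tails": self.tails,
        }


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table, dtype=int)
    if arr.shape == (2, 2):
        return ContingencyTable2x2(*arr.ravel().tolist())
    if arr.shape == (4,):
        return ContingencyTable2x2(*arr.tolist())
    raise ValueError("expected a 2x2 table or 4 counts (a, b, c, d)")


def chi2_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the optional Yates
    continuity correction subtracts n/2 from |ad - bc|.  The odds ratio is
    attached as the effect size (None for zero off-diagonal cells).
    """
    t = _as_table(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined: a zero margin in the 2x2 table")
    n = t.n
    num = abs(a * d - b * c)
    if correction:
        num = max(0.0, num - n / 2.0)
    chi2 = n * num**2 / margins
    return TestResult(
        statistic=float(chi2),
        df=1.0,
        p=float(sps.chi2.sf(chi2, 1)),
        effect_size=t.odds_ratio(),
        method="pearson-chi2" + ("-yates" if correction else ""),
        tails=2,
    )


def fisher_exact(table, tails: int = 2) -> TestResult:
    """Fisher's exact hypergeometric test on a 2x2 table.

    One-tailed tests enrichment of cell a given the margins; the
    two-tailed p sums all tables as or less probable than the observed one.
    """
    t = _as_table(table)
    arr = np.array([[t.a, t.b], [t.c, t.d]])
    if tails == 1:
        _, p = sps.fisher_exact(arr, alternative="greater")
    elif tails == 2:
        _, p = sps.fisher_exact(arr, alternative="two-sided")
    else:
        raise ValueError("tails must be 1 or 2")
    return TestResult(
        statistic=float(t.a),
        p=float(p),
        effect_size=t.odds_ratio(),
        method="fisher-exact",
        tails=tails,
    )


def mcnemar(discordant_b: int, discordant_c: int) -> TestResult:
    """McNemar's chi-square for paired proportions, without continuity
    correction: chi2 = (b - c)^2 / (b + c), df = 1.

    Only the discordant pair counts enter the statistic.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise ValueError("McNemar undefined: no discordant pairs")
    chi2 = (b - c) ** 2 / (b + c)
    return TestResult(
        statistic=float(chi2),
        df=1.0,
        p=float(sps.chi2.sf(chi2, 1)),
        method="mcnemar",
        tails=2,
    )


def ttest_pooled(
    mean_a=None, sd_a=None, n_a=None, mean_b=None, sd_b=None, n_b=None,
    *, scores_a: Sequence[float] | None = None, scores_b: Sequence[float] | None = None,
) -> TestResult:
    """Student two-sample t-test with pooled variance, plus Cohen's d.

    Accepts either summary statistics (mean, SD, n per group) or raw score
    vectors.  df = n_a + n_b - 2; d = |mean difference| / pooled SD.
    """
    if scores_a is not None or scores_b is not None:
        xa = np.asarray(scores_a, dtype=float)
        xb = np.asarray(scores_b, dtype=float)
        mean_a, sd_a, n_a = xa.mean(), xa.std(ddof=1), xa.size
        mean_b, sd_b, n_b = xb.mean(), xb.std(ddof=1), xb.size
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 in each group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if pooled_var == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, "pooled-t", df=float(df), effect_size=0.0)
        raise ValueError("zero pooled variance with unequal means")
    pooled_sd = math.sqrt(pooled_var)
    t = diff / (pooled_sd * math.sqrt(1.0 / n_a + 1.0 / n_b))
    d = abs(diff) / pooled_sd
    return TestResult(
        statistic=float(t),
        df=float(df),
        p=float(2 * sps.t.sf(abs(t), df)),
        effect_size=float(d),
        method="pooled-t",
        tails=2,
    )


def compare_dependent_correlations(r_xy: float, r_xz: float, r_yz: float, n: int) -> TestResult:
    """Meng-Rosenthal-Rubin z for two correlations sharing variable x.

    Tests whether x correlates more strongly with y than with z, given the
    y-z correlation, via Fisher-z transformed correlations.
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation out of range: {r}")
    if n < 4:
        raise ValueError("need n >= 4")
    corr = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("correlations do not form a positive semidefinite matrix")
    r2bar = (r_xy**2 + r_xz**2) / 2.0
    f = min(1.0, (1.0 - r_yz) / (2.0 * (1.0 - r2bar))) if r2bar < 1 else 1.0
    h = (1.0 - f * r2bar) / (1.0 - r2bar) if r2bar < 1 else 1.0
    z_xy = np.arctanh(r_xy)
    z_xz = np.arctanh(r_xz)
    z = (z_xy - z_xz) * math.sqrt((n - 3) / (2.0 * (1.0 - r_yz) * h))
    return TestResult(
        statistic=float(z),
        p=float(2 * sps.norm.sf(abs(z))),
        method="meng-rosenthal-rubin-z",
        tails=2,
    )


def compare_paired_predictive_values(
    test_a: Sequence[bool], test_b: Sequence[bool], impaired: Sequence[bool]
) -> dict[str, TestResult]:
    """Compare PPV and NPV of two binary classifiers measured on the same
    patients (paired design).

    Estimates the relative predictive values rPPV = PPV_A / PPV_B and
    rNPV = NPV_A / NPV_B with an asymptotic variance of the log-ratio from
    the joint (paired) empirical distribution, and tests log-ratio = 0 with
    a z statistic.  Returns {"ppv": TestResult, "npv": TestResult}; the
    effect size carries the ratio.
    """
    xa = np.asarray(test_a, dtype=bool)
    xb = np.asarray(test_b, dtype=bool)
    dz = np.asarray(impaired, dtype=bool)
    if not (xa.shape == xb.shape == dz.shape) or xa.size == 0:
        raise ValueError("indicators must be equal-length and non-empty")
    n = xa.size

    def _ratio(pos_a, pos_b, outcome) -> TestResult:
        if pos_a.sum() == 0 or pos_b.sum() == 0:
            raise ValueError("a test has no positives: predictive value undefined")
        pv_a = (pos_a & outcome).sum() / pos_a.sum()
        pv_b = (pos_b & outcome).sum() / pos_b.sum()
        if pv_a == 0 or pv_b == 0:
            raise ValueError("a predictive value is zero: log-ratio undefined")
        ratio = pv_a / pv_b
        # influence function of log(pv_a) - log(pv_b) under the paired
        # multinomial: phi_i = (u_i/mu_u - v_i/mu_v) - (s_i/mu_s - t_i/mu_t)
        u = (pos_a & outcome).astype(float)
        v = pos_a.astype(float)
        s = (pos_b & outcome).astype(float)
        t = pos_b.astype(float)
        phi = u / u.mean() - v / v.mean() - s / s.mean() + t / t.mean()
        var = phi.var(ddof=0) / n
        if var == 0:
            z = 0.0
        else:
            z = math.log(ratio) / math.sqrt(var)
        return TestResult(
            statistic=float(z),
            p=float(2 * sps.norm.sf(abs(z))),
            effect_size=float(ratio),
            method="paired-relative-predictive-value",
            tails=2,
        )

    return {
        "ppv": _ratio(xa, xb, dz),
        "npv": _ratio(~xa, ~xb, ~dz),
    }


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) per value (m defaults to the
    number of p-values)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of range: {p}")
        out.append(min(1.0, m * p))
    return out
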