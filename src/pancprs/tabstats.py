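"""Contingency-table and two-sample machinery for the epidemiology and
ancestry allele-frequency comparisons, including reconstruction of integer
counts from printed percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import reported_epidemiology


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # chisq | fisher | t
    statistic: float
    p: float
    detail: object = None  # underlying counts table or (mean, sd, n) pairs


def chisq_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r×c count table, no continuity correction.

    Returns ``(statistic, df, p)``; a zero row or column margin is a hard
    error because expected counts are then undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise StatsError("chi-square needs a 2-D table of non-negative counts")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise StatsError("degenerate margin: a row or column sums to zero")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    The p-value is the total hypergeometric probability of all tables with
    the observed margins whose probability does not exceed the observed
    table's.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("Fisher exact needs a 2×2 table of non-negative integers")
    a, b, c, d = (int(v) for v in t.ravel())
    n = a + b + c + d
    if n == 0:
        raise StatsError("Fisher exact needs at least one non-zero cell")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    # relative slack absorbs float noise when summing "as extreme" tables
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def two_sample_t(
    mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
    *, sample1=None, sample2=None, welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from raw samples or summary moments.

    Pooled-variance Student t by default; ``welch=True`` drops the equal-
    variance assumption.  Returns ``(t, df, p)``.
    """
    if sample1 is not None:
        sample1 = np.asarray(sample1, float)
        sample2 = np.asarray(sample2, float)
        mean1, sd1, n1 = sample1.mean(), sample1.std(ddof=1), sample1.size
        mean2, sd2, n2 = sample2.mean(), sample2.std(ddof=1), sample2.size
    if n1 < 2 or n2 < 2:
        raise StatsError("t-test needs at least two observations per group")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


def counts_from_percent(pct: float, denominator: int) -> int:
    """Nearest-integer count implied by a printed percentage.

    Rounds half away from zero (so 50% of 5 → 3), matching the convention
    that reproduces the published cells.
    """
    if not 0 <= pct <= 100:
        raise StatsError(f"percentage {pct} outside [0, 100]")
    if denominator <= 0:
        raise StatsError("denominator must be positive")
    count = math.floor(pct / 100 * denominator + 0.5)
    if not 0 <= count <= denominator:
        raise StatsError(f"reconstructed count {count} outside [0, {denominator}]")
    return count


def allele_count_table(maf1: float, n1_subjects: int, maf2: float, n2_subjects: int) -> np.ndarray:
    """2×2 minor/major allele count table for two groups of diploid subjects.

    Allele totals are 2·n subjects; minor counts come from rounding the
    printed frequency to the nearest whole allele.
    """
    for maf in (maf1, maf2):
        if not 0 <= maf <= 1:
            raise StatsError(f"MAF {maf} outside [0, 1]")
    if n1_subjects <= 0 or n2_subjects <= 0:
        raise StatsError("subject counts must be positive")
    a1, a2 = 2 * n1_subjects, 2 * n2_subjects
    m1 = counts_from_percent(100 * maf1, a1)
    m2 = counts_from_percent(100 * maf2, a2)
    return np.array([[m1, a1 - m1], [m2, a2 - m2]])


def allele_count_test(
    maf1: float, n1_subjects: int, maf2: float, n2_subjects: int, method: str = "chisq"
) -> tuple[np.ndarray, float]:
    """Compare two allele frequencies via the reconstructed 2×2 allele table."""
    table = allele_count_table(maf1, n1_subjects, maf2, n2_subjects)
    if method == "chisq":
        _, _, p = chisq_test(table)
    elif method == "fisher":
        p = fisher_exact(table)
    else:
        raise StatsError(f"unknown method {method!r}")
    return table, p


# Effective denominators for the published exposure percentages: the smallest
# integers that reproduce every printed cell (enrollment was 78/256; the
# discrepancy is surfaced, not hidden).
EFFECTIVE_N_CASES = 76
EFFECTIVE_N_CONTROLS = 260


def epidemiology_comparisons(
    subjects=None, *, n_cases: int | None = None, n_controls: int | None = None
) -> list[GroupComparison]:
    """Case/control comparisons of the epidemiological variables.

    With ``subjects`` given, computes from the cohort (chi-square for the
    categorical variables, Student t for age).  Without, reconstructs counts
    from the shipped published percentages at the effective denominators and
    reproduces the published tests.
    """
    if subjects is not None:
        return _epidemiology_from_subjects(subjects)
    n_ca = EFFECTIVE_N_CASES if n_cases is None else n_cases
    n_co = EFFECTIVE_N_CONTROLS if n_controls is None else n_controls
    table1 = reported_epidemiology()
    out = []
    for variable, grp in table1.groupby("variable", sort=False):
        counts = np.array(
            [
                [counts_from_percent(p, n_ca) for p in grp["pct_cases"]],
                [counts_from_percent(p, n_co) for p in grp["pct_controls"]],
            ]
        )
        stat, _, p = chisq_test(counts)
        out.append(GroupComparison(variable, "chisq", stat, p, counts))
    return out


def _epidemiology_from_subjects(subjects) -> list[GroupComparison]:
    from .panel import EXPOSURES

    out = []
    cases = [s for s in subjects if s.is_case]
    controls = [s for s in subjects if not s.is_case]
    age_ca = [s.age for s in cases if s.age is not None]
    age_co = [s.age for s in controls if s.age is not None]
    if len(age_ca) >= 2 and len(age_co) >= 2:
        t, _, p = two_sample_t(sample1=age_ca, sample2=age_co)
        out.append(GroupComparison("age", "t", t, p,
                                   ((np.mean(age_ca), np.std(age_ca, ddof=1), len(age_ca)),
                                    (np.mean(age_co), np.std(age_co, ddof=1), len(age_co)))))

    def cat_table(getter, levels):
        return np.array(
            [[sum(1 for s in grp if getter(s) == lv) for lv in levels] for grp in (cases, controls)]
        )

    for variable, getter, levels in [
        ("sex", lambda s: s.sex, ("male", "female")),
        ("ethnicity", lambda s: s.ancestry, ("African", "European", "Asian")),
    ] + [
        (exp, (lambda s, e=exp: s.exposures.get(e)), ("yes", "no")) for exp in EXPOSURES
    ]:
        counts = cat_table(getter, levels)
        counts = counts[:, counts.sum(axis=0) > 0]
        if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
            continue
        stat, _, p = chisq_test(counts)
        out.append(GroupComparison(variable, "chisq", stat, p, counts))
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variable": c.variable, "test": c.test, "statistic": c.statistic, "p": c.p}
         for c in comparisons]
    )
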