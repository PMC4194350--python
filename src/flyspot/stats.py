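"""Group statistics for plate-level variables.

Plates are grouped into user-defined comparison groups; each selected
variable is compared between pairs of groups with either Student's
(pooled-variance) t-test or the Mann–Whitney U test, with Jarque–Bera
normality p-values reported per group as guidance for the choice (never
auto-switching).  Raw p-values from one comparison call form one family
and are adjusted with the Holm–Bonferroni step-down correction; the
correction is skippable, which matters when trying to demonstrate a
*lack* of effect (over-conservative adjustment inflates type II error).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plate import PlateSummary

logger = logging.getLogger(__name__)

__all__ = [
    "Descriptives",
    "JarqueBeraResult",
    "ComparisonResult",
    "descriptive",
    "jarque_bera",
    "student_t",
    "mann_whitney_u",
    "holm_bonferroni",
    "summaries_to_frame",
    "group_descriptives",
    "compare_groups",
]


class Descriptives(NamedTuple):
    mean: float
    sd: float
    median: float
    min: float
    max: float


class JarqueBeraResult(NamedTuple):
    statistic: float
    pvalue: float
    small_sample: bool  # asymptotic p unreliable below n = 30


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float | None = None


@dataclass
class ComparisonResult:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float
    raw_p: float
    adjusted_p: float
    normality_p_a: float
    normality_p_b: float

    def to_row(self) -> dict[str, object]:
        return dict(vars(self))


def descriptive(values: Sequence[float]) -> Descriptives:
    """Mean, sample SD (n−1), median, min, max.  SD is NaN for n = 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("descriptive statistics need at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return Descriptives(
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def jarque_bera(values: Sequence[float]) -> JarqueBeraResult:
    """Jarque–Bera normality test.

    JB = n/6 · (S² + (K − 3)²/4) with S and K the sample skewness and
    kurtosis from biased central moments; p from the asymptotic χ²(2)
    law.  The ``small_sample`` flag marks n < 30, where the asymptotic p
    is a poor guide.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 4:
        raise ValueError("Jarque-Bera needs at least 4 observations")
    m = arr.mean()
    m2 = ((arr - m) ** 2).mean()
    if m2 == 0:
        raise ValueError("Jarque-Bera is undefined for zero-variance data")
    m3 = ((arr - m) ** 3).mean()
    m4 = ((arr - m) ** 4).mean()
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    jb = n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0)
    p = float(sps.chi2.sf(jb, df=2))
    return JarqueBeraResult(float(jb), p, small_sample=n < 30)


def student_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample pooled-variance Student's t-test (two-sided).

    df = n_a + n_b − 2.  Degenerate inputs: two zero-variance groups with
    equal means give t = 0, p = 1; zero pooled variance with unequal
    means gives an infinite statistic and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Student's t-test needs at least 2 values per group")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, df)
        return TestResult(math.copysign(math.inf, a.mean() - b.mean()), 0.0, df)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue), df)


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test, offered as an alternative."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least 2 values per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a_i > b_j) pairs plus half the tied pairs."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


EXACT_LIMIT = 16  # combined n at or below which the exact null is enumerated


def _exact_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Every C(n_a+n_b, n_a) split of the pooled sample is equally likely
    under the null; p doubles the smaller tail, capped at 1.
    """
    pooled = np.concatenate([a, b])
    n_a = a.size
    us = np.array(
        [
            _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in itertools.combinations(range(pooled.size), n_a)
        ]
    )
    u_small = min(u, a.size * b.size - u)
    tail = (us <= u_small + 1e-9).mean()
    return min(1.0, 2.0 * float(tail))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mann–Whitney U test (two-sided) for group a.

    U counts (a_i, b_j) pairs won by a plus half the ties, so that
    U_a + U_b = n_a·n_b.  The p-value is exact (full enumeration of rank
    assignments) when n_a + n_b <= 16 and there are no ties — cheap at
    the plate-group sizes typical of this assay (6–8 replicates) —
    otherwise a normal approximation with tie and continuity corrections
    is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("Mann-Whitney needs at least 1 value per group")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_LIMIT and not has_ties:
        return TestResult(u, _exact_p(a, b, u))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(u, float(res.pvalue))


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Holm–Bonferroni step-down adjustment, returned in the input order.

    Sorted ascending, p(i) is multiplied by (m − i), then made monotone
    non-decreasing down the sorted order and capped at 1.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, arr[idx] * (m - rank))
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def summaries_to_frame(summaries: Iterable[PlateSummary]) -> pd.DataFrame:
    """Flatten plate summaries to one row per plate (subset-prefixed columns)."""
    return pd.DataFrame([s.to_row() for s in summaries])


def _collect(
    frame: pd.DataFrame, plate_ids: Sequence[str], variable: str
) -> np.ndarray:
    if variable not in frame.columns:
        raise KeyError(f"unknown variable {variable!r}")
    sub = frame[frame["plate_id"].isin(list(plate_ids))]
    missing = set(plate_ids) - set(sub["plate_id"])
    if missing:
        raise KeyError(f"unknown plate ids {sorted(missing)!r}")
    vals = sub[variable].to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info(
            "variable %s: skipped %d plate(s) with missing values", variable, n_missing
        )
    return vals[~np.isnan(vals)]


def group_descriptives(
    summaries: Iterable[PlateSummary],
    groups: Mapping[str, Sequence[str]],
    variables: Sequence[str],
) -> pd.DataFrame:
    """Descriptive statistics (mean, SD, median, min, max) per group and variable."""
    frame = summaries_to_frame(summaries)
    rows = []
    for group, plate_ids in groups.items():
        for var in variables:
            vals = _collect(frame, plate_ids, var)
            if vals.size == 0:
                continue
            d = descriptive(vals)
            rows.append({"group": group, "variable": var, "n": vals.size, **d._asdict()})
    return pd.DataFrame(rows)


_TESTS = {"student_t": student_t, "welch_t": welch_t, "mann_whitney": mann_whitney_u}


def compare_groups(
    summaries: Iterable[PlateSummary],
    groups: Mapping[str, Sequence[str]],
    variables: Sequence[str],
    test: str = "student_t",
    correct: bool = True,
) -> list[ComparisonResult]:
    """Pairwise group comparison for each selected plate-level variable.

    One result per (variable, group pair); the Holm family is the full
    set of comparisons in this call when ``correct`` is true, otherwise
    adjusted_p equals raw_p.  Jarque–Bera normality p-values are
    reported per group (NaN when not computable) as guidance only.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {sorted(_TESTS)}")
    frame = summaries_to_frame(summaries)
    test_fn = _TESTS[test]
    results: list[ComparisonResult] = []
    for var in variables:
        for ga, gb in itertools.combinations(groups, 2):
            va = _collect(frame, groups[ga], var)
            vb = _collect(frame, groups[gb], var)
            res = test_fn(va, vb)
            norm = []
            for v in (va, vb):
                try:
                    norm.append(jarque_bera(v).pvalue)
                except ValueError:
                    norm.append(math.nan)
            results.append(
                ComparisonResult(
                    variable=var,
                    group_a=ga,
                    group_b=gb,
                    n_a=va.size,
                    n_b=vb.size,
                    test=test,
                    statistic=res.statistic,
                    raw_p=res.pvalue,
                    adjusted_p=res.pvalue,
                    normality_p_a=norm[0],
                    normality_p_b=norm[1],
                )
            )
    if correct and results:
        for r, adj in zip(results, holm_bonferroni([r.raw_p for r in results])):
            r.adjusted_p = adj
    return results
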