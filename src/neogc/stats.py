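"""Association statistics: one-sided rank-sum comparisons and the OLS fit.

The rank-sum convention used throughout is fixed deliberately and recorded
on every result: midranks for ties, the Mann-Whitney U statistic for group
A, tie-corrected variance

    var(U) = (n_a n_b / 12) * [(n + 1) - sum(t^3 - t) / (n (n - 1))],

z = (U - n_a n_b / 2) / sd with NO continuity correction, and a one-sided
p-value from the normal tail. An exact-permutation mode and a continuity
correction remain available behind flags for sensitivity checks. No
multiple-testing correction is applied by default (raw p-values are
reported); a Benjamini-Hochberg helper is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

Alternative = Literal["a_greater", "a_less"]

METHOD_DESC = "rank-sum, normal approximation, no continuity correction, tie-corrected variance"


class DegenerateDataError(ValueError):
    """All pooled values identical: the rank-sum statistic has zero variance."""


@dataclass(frozen=True)
class TestResult:
    """One two-group comparison."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u: float
    z: float
    p: float
    alternative: Alternative
    method: str = METHOD_DESC


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U for group a (midranks) and the tie-corrected variance of U."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    return u, var


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float, alternative: Alternative) -> float:
    """Exact permutation p-value by full enumeration of group-A index sets."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    offset = n_a * (n_a + 1) / 2.0
    n_ge = n_le = 0
    total = comb(len(pooled), n_a)
    for idx in combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - offset
        if u >= u_obs - 1e-9:
            n_ge += 1
        if u <= u_obs + 1e-9:
            n_le += 1
    return (n_ge if alternative == "a_greater" else n_le) / total


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Alternative = "a_greater",
    *,
    exact: bool = False,
    continuity: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> TestResult:
    """One-sided two-sample rank-sum test under the documented convention."""
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(av) == 0 or len(bv) == 0:
        raise ValueError("both groups must be non-empty")
    u, var = _u_statistic(av, bv)
    if var <= 0:
        raise DegenerateDataError("all pooled values identical; rank-sum variance is zero")
    mu = len(av) * len(bv) / 2.0
    cc = 0.0
    if continuity:
        cc = 0.5 if alternative == "a_greater" else -0.5
    z = (u - mu - cc) / np.sqrt(var)
    if exact:
        p = _exact_p(av, bv, u, alternative)
    else:
        p = float(sps.norm.sf(z) if alternative == "a_greater" else sps.norm.cdf(z))
    return TestResult(
        label_a=label_a,
        label_b=label_b,
        n_a=len(av),
        n_b=len(bv),
        median_a=float(np.median(av)),
        median_b=float(np.median(bv)),
        u=float(u),
        z=float(z),
        p=p,
        alternative=alternative,
        method=METHOD_DESC + (" [exact]" if exact else "") + (" [continuity]" if continuity else ""),
    )


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x; R^2 is the squared Pearson correlation."""
    xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xv) < 3 or len(xv) != len(yv):
        raise ValueError("need at least 3 paired points")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(xv, yv)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


T_STAGE_ORDER = ("T1a", "T1b", "T2", "T3", "T4a", "T4b")

AGE_SPLIT = 45  # "younger" means age <= 45


def subgroup_report(
    summaries,
    clinical,
    grouping: Literal["age45", "sex", "t_stage"],
    *,
    min_group: int = 2,
    exact: bool = False,
    continuity: bool = False,
) -> list[TestResult]:
    """Compare neoantigen burden across clinical subgroups.

    * ``age45`` — patients older than 45 vs age <= 45; alternative: older
      group has greater burden.
    * ``sex`` — male vs female; alternative: male greater.
    * ``t_stage`` — all pairwise comparisons among stages present, in stage
      order; alternative: the earlier stage has greater burden.

    Comparisons where either group has fewer than ``min_group`` members are
    skipped with a logged warning.
    """
    neo = {s.patient_id: s.n_neoantigen for s in summaries}
    missing = [p.patient_id for p in clinical if p.patient_id not in neo]
    if missing:
        raise ValueError(f"patients without summaries: {missing}")

    def values(pred):
        return [neo[p.patient_id] for p in clinical if pred(p)]

    kwargs = dict(exact=exact, continuity=continuity)
    pairs: list[tuple[str, list[float], str, list[float]]] = []
    if grouping == "age45":
        pairs.append(
            (
                f"age>{AGE_SPLIT}",
                values(lambda p: p.age > AGE_SPLIT),
                f"age<={AGE_SPLIT}",
                values(lambda p: p.age <= AGE_SPLIT),
            )
        )
    elif grouping == "sex":
        pairs.append(("M", values(lambda p: p.sex == "M"), "F", values(lambda p: p.sex == "F")))
    elif grouping == "t_stage":
        present = [s for s in T_STAGE_ORDER if any(p.t_stage == s for p in clinical)]
        for early, late in combinations(present, 2):
            pairs.append(
                (
                    early,
                    values(lambda p, s=early: p.t_stage == s),
                    late,
                    values(lambda p, s=late: p.t_stage == s),
                )
            )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    results = []
    for la, va, lb, vb in pairs:
        if len(va) < min_group or len(vb) < min_group:
            logger.warning(
                "skipping %s vs %s: group sizes %d/%d below %d", la, lb, len(va), len(vb), min_group
            )
            continue
        results.append(rank_sum_test(va, vb, "a_greater", label_a=la, label_b=lb, **kwargs))
    return results


def adjust_bh(results: Sequence[TestResult]) -> Mapping[tuple[str, str], float]:
    """Benjamini-Hochberg adjusted p-values keyed by comparison labels.

    Off by default everywhere; provided for users who report many
    comparisons at once.
    """
    ps = np.array([r.p for r in results])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, ps[i] * m / (rank_idx + 1))
        adj[i] = running
    return {(r.label_a, r.label_b): float(adj[i]) for i, r in enumerate(results)}
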