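"""Rank-sum convention, OLS fit, and subgroup reports."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from neogc.stats import (
    DegenerateDataError,
    adjust_bh,
    fit_linear,
    rank_sum_test,
    subgroup_report,
)
from neogc.types import Patient, PatientSummary


def exact_oracle(a, b, alternative="a_greater"):
    """Independent full-enumeration permutation p-value (midranks)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    offset = na * (na + 1) / 2
    u_obs = ranks[:na].sum() - offset
    hits = 0
    for idx in combinations(range(len(pooled)), na):
        u = ranks[list(idx)].sum() - offset
        ok = u >= u_obs - 1e-9 if alternative == "a_greater" else u <= u_obs + 1e-9
        hits += ok
    return hits / comb(len(pooled), na)


class TestRankSum:
    def test_identical_groups_give_central_p(self):
        r = rank_sum_test([1, 2, 3], [1, 2, 3], "a_greater")
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(0.5)

    def test_matches_scipy_asymptotic_no_continuity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 30, rng.integers(3, 12)).astype(float)
            b = rng.integers(0, 30, rng.integers(3, 12)).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            ours = rank_sum_test(a, b, "a_greater")
            ref = sps.mannwhitneyu(
                a, b, alternative="greater", use_continuity=False, method="asymptotic"
            )
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)
            assert ours.u == pytest.approx(ref.statistic)

    def test_exact_mode_equals_independent_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = rng.integers(0, 8, rng.integers(2, 7)).astype(float)
            b = rng.integers(0, 8, rng.integers(2, 7)).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            for alt in ("a_greater", "a_less"):
                ours = rank_sum_test(a, b, alt, exact=True)
                assert ours.p == pytest.approx(exact_oracle(a, b, alt), abs=1e-12)

    def test_label_swap_with_mirrored_alternative_is_identical(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=8)
        b = rng.normal(size=5)
        assert rank_sum_test(a, b, "a_greater").p == pytest.approx(
            rank_sum_test(b, a, "a_less").p, rel=1e-12
        )

    def test_tie_free_variance_reduces_to_classic_formula(self):
        from neogc.stats import _u_statistic

        rng = np.random.default_rng(3)
        a, b = rng.normal(size=7), rng.normal(size=9)
        _, var = _u_statistic(a, b)
        n = 16
        assert var == pytest.approx(7 * 9 * (n + 1) / 12)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            rank_sum_test([5, 5], [5, 5, 5], "a_greater")
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0], "a_greater")

    def test_continuity_correction_shifts_toward_center(self):
        a, b = [5.0, 6.0, 9.0], [1.0, 2.0, 3.0, 4.0]
        plain = rank_sum_test(a, b, "a_greater")
        cc = rank_sum_test(a, b, "a_greater", continuity=True)
        assert cc.p > plain.p

    def test_null_rejection_rate_is_five_percent(self):
        # 10,000 seeded two-group draws of 20+20 from one distribution;
        # vectorised re-implementation of the same convention
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10000, 40))
        ranks = sps.rankdata(x, axis=1)
        u = ranks[:, :20].sum(axis=1) - 20 * 21 / 2
        z = (u - 200.0) / np.sqrt(20 * 20 * 41 / 12)
        rate = (sps.norm.sf(z) < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)
        # spot-check the vectorisation against the implementation
        r = rank_sum_test(x[0, :20], x[0, 20:], "a_greater")
        assert r.z == pytest.approx(z[0])


class TestLinearFit:
    def test_collinear_points_have_unit_r_squared(self):
        fit = fit_linear([1, 2, 3, 4], [3, 5, 7, 9])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_r_squared_equals_squared_pearson_correlation(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = 2 * x + rng.normal(size=n)
            fit = fit_linear(x, y)
            assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-9)

    def test_constant_x_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])


def _cohort(rows):
    clinical, summaries = [], []
    for pid, sex, age, tnm, neo in rows:
        clinical.append(Patient(pid, sex, age, tnm))
        summaries.append(PatientSummary.from_counts(pid, 10, 1, neo))
    return summaries, clinical


class TestSubgroupReport:
    def test_small_groups_are_skipped_with_warning(self, caplog):
        rows = [
            ("P1", "M", 60, "T1aN0M0", 100),
            ("P2", "M", 60, "T2N0M0", 50),
            ("P3", "M", 61, "T2N0M0", 60),
        ]
        with caplog.at_level("WARNING", logger="neogc.stats"):
            results = subgroup_report(*_cohort(rows), "t_stage")
        assert results == []
        assert "skipping" in caplog.text

    def test_medians_attached_and_alternatives_fixed(self):
        rows = [
            ("P1", "M", 60, "T2N0M0", 100),
            ("P2", "M", 50, "T2N0M0", 120),
            ("P3", "F", 44, "T2N0M0", 30),
            ("P4", "F", 40, "T2N0M0", 20),
        ]
        (res,) = subgroup_report(*_cohort(rows), "sex")
        assert (res.label_a, res.label_b) == ("M", "F")
        assert res.median_a == 110 and res.median_b == 25
        (res,) = subgroup_report(*_cohort(rows), "age45")
        assert res.label_a == "age>45" and res.n_a == 2

    def test_unknown_grouping_rejected(self):
        rows = [("P1", "M", 60, "T2N0M0", 1), ("P2", "F", 50, "T2N0M0", 2)]
        with pytest.raises(ValueError):
            subgroup_report(*_cohort(rows), "histology")


class TestBH:
    def test_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=6)
        results = [
            rank_sum_test(a + shift, b, "a_greater", label_a=f"s{shift}")
            for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        adj = adjust_bh(results)
        raw = {(r.label_a, r.label_b): r.p for r in results}
        for key, p_adj in adj.items():
            assert raw[key] <= p_adj <= 1.0
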