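"""Contingency machinery, Fisher exact, chi-square, t-test, Kaplan-Meier and
log-rank — each checked against an independent oracle (exact rational
arithmetic, scipy, or lifelines)."""

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as scipy_stats

from lynchmod.association import (
    ContingencyTable,
    KMCurve,
    SurvivalRecord,
    burden_table,
    dichotomize,
    fisher_exact_2x2,
    kaplan_meier,
    load_published_burden_distribution,
    log_rank,
    pearson_chi_square,
    two_sample_t,
)
from lynchmod.curation import BurdenProfile
from lynchmod.errors import DegenerateTableError


def _comb(n, k):
    return math.comb(n, k)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by probability-mass ordering in exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = _comb(n, c1)
    pmf = {
        x: Fraction(_comb(r1, x) * _comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestContingencyTable:
    def test_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a",), ("x", "y"), ((1, 2),))
        with pytest.raises(ValueError):
            ContingencyTable(("a", "b"), ("x", "y"), ((1, 2), (3, -1)))

    def test_margins(self):
        t = ContingencyTable(("a", "b"), ("x", "y"), ((1, 2), (3, 4)))
        rows, cols = t.margins()
        assert list(rows) == [3, 7]
        assert list(cols) == [4, 6]


class TestBurdenTable:
    def _profiles(self, burdens):
        return [
            BurdenProfile(f"s{i}", b, 0, ()) for i, b in enumerate(burdens)
        ]

    def test_cross_tabulation(self):
        profiles = self._profiles([0, 0, 1, 2, 3])
        phen = {"s0": "neutral", "s1": "poor", "s2": "poor", "s3": "neutral", "s4": "poor"}
        t = burden_table(profiles, phen)
        assert t.row_labels == ("0", "1", "2", "3")
        assert t.counts == ((1, 1), (0, 1), (1, 0), (0, 1))

    def test_pooled_top_row(self):
        t = burden_table(self._profiles([0, 5, 7]), {"s0": "poor", "s1": "poor", "s2": "neutral"}, max_count=3)
        assert t.row_labels[-1] == "3+"
        assert t.counts[-1] == (1, 1)

    def test_missing_phenotype_rejected(self):
        with pytest.raises(DegenerateTableError, match="s1"):
            burden_table(self._profiles([0, 1]), {"s0": "poor"})

    def test_grand_total_preserved(self):
        rng = random.Random(3)
        burdens = [rng.randint(0, 4) for _ in range(40)]
        phen = {f"s{i}": rng.choice(["poor", "neutral"]) for i in range(40)}
        t = burden_table(self._profiles(burdens), phen)
        assert t.matrix.sum() == 40


class TestDichotomize:
    def test_margin_preservation_at_every_k(self):
        t = load_published_burden_distribution()
        for k in range(1, 6):
            two = dichotomize(t, k)
            assert list(two.matrix.sum(axis=0)) == list(t.matrix.sum(axis=0))
            assert two.matrix.sum() == t.matrix.sum()
            assert list(two.matrix[0]) == list(t.matrix[:k].sum(axis=0))

    def test_published_distribution_at_default_cut(self):
        two = dichotomize(load_published_burden_distribution(), 2)
        assert two.counts == ((11, 6), (2, 16))

    def test_invalid_k_rejected(self):
        t = load_published_burden_distribution()
        with pytest.raises(DegenerateTableError):
            dichotomize(t, 0)
        with pytest.raises(DegenerateTableError):
            dichotomize(t, 6)


class TestFisherExact:
    def test_matches_exact_rational_oracle_on_random_tables(self):
        rng = random.Random(17)
        for _ in range(300):
            a, b, c, d = (rng.randint(0, 25) for _ in range(4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = ContingencyTable(("r0", "r1"), ("c0", "c1"), ((a, b), (c, d)))
            got = fisher_exact_2x2(t).p_value
            want = fisher_oracle(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-10), (a, b, c, d)

    def test_matches_scipy_on_random_tables(self):
        rng = random.Random(23)
        for _ in range(200):
            a, b, c, d = (rng.randint(0, 20) for _ in range(4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = ContingencyTable(("r0", "r1"), ("c0", "c1"), ((a, b), (c, d)))
            got = fisher_exact_2x2(t).p_value
            want = scipy_stats.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(want, rel=1e-9), (a, b, c, d)

    def test_transpose_invariance(self):
        rng = random.Random(5)
        for _ in range(50):
            a, b, c, d = (rng.randint(1, 15) for _ in range(4))
            p1 = fisher_exact_2x2(
                ContingencyTable(("r0", "r1"), ("c0", "c1"), ((a, b), (c, d)))
            ).p_value
            p2 = fisher_exact_2x2(
                ContingencyTable(("c0", "c1"), ("r0", "r1"), ((a, c), (b, d)))
            ).p_value
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_hypergeometric_mass_sums_to_one(self):
        from lynchmod.association import _log_hypergeom_pmf

        rng = random.Random(9)
        for _ in range(50):
            r1, r2 = rng.randint(1, 40), rng.randint(1, 40)
            c1 = rng.randint(1, r1 + r2 - 1)
            lo, hi = max(0, c1 - r2), min(r1, c1)
            total = sum(
                math.exp(_log_hypergeom_pmf(x, r1, r2, c1)) for x in range(lo, hi + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_independence_gives_p_one(self):
        t = ContingencyTable(("r0", "r1"), ("c0", "c1"), ((5, 10), (10, 20)))
        assert fisher_exact_2x2(t).p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        t = ContingencyTable(("r0", "r1"), ("c0", "c1"), ((0, 5), (0, 7)))
        with pytest.raises(DegenerateTableError):
            fisher_exact_2x2(t)

    def test_requires_2x2(self):
        t = load_published_burden_distribution()
        with pytest.raises(DegenerateTableError):
            fisher_exact_2x2(t)


class TestChiSquare:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            shape = (rng.integers(2, 5), rng.integers(2, 4))
            m = rng.integers(1, 40, size=shape)
            t = ContingencyTable(
                tuple(f"r{i}" for i in range(shape[0])),
                tuple(f"c{j}" for j in range(shape[1])),
                tuple(map(tuple, m.tolist())),
            )
            with pytest.warns(UserWarning) if (np.outer(m.sum(1), m.sum(0)) / m.sum() < 5).any() else _nullcontext():
                got = pearson_chi_square(t)
            stat, p, df, _ = scipy_stats.chi2_contingency(m, correction=False)
            assert got.statistic == pytest.approx(stat, rel=1e-12)
            assert got.df == df
            assert got.p_value == pytest.approx(p, rel=1e-10, abs=1e-300)

    def test_row_permutation_invariance(self):
        m = [(5, 6), (1, 1), (0, 4), (2, 9)]
        labels = ("a", "b", "c", "d")
        base = None
        for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2]):
            t = ContingencyTable(
                tuple(labels[i] for i in perm),
                ("x", "y"),
                tuple(m[i] for i in perm),
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = pearson_chi_square(t)
            if base is None:
                base = r.statistic
            assert r.statistic == pytest.approx(base, rel=1e-12)

    def test_small_expected_counts_warn(self):
        t = ContingencyTable(("a", "b"), ("x", "y"), ((1, 2), (3, 4)))
        with pytest.warns(UserWarning, match="below 5"):
            pearson_chi_square(t)


import contextlib


def _nullcontext():
    return contextlib.nullcontext()


class TestTwoSampleT:
    def test_matches_scipy_pooled_and_welch(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            x = rng.normal(0, 1, size=rng.integers(3, 30))
            y = rng.normal(0.4, 1.5, size=rng.integers(3, 30))
            got = two_sample_t(x, y)
            ref = scipy_stats.ttest_ind(x, y)
            assert got.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert got.p_value == pytest.approx(ref.pvalue, rel=1e-10)
            gotw = two_sample_t(x, y, welch=True)
            refw = scipy_stats.ttest_ind(x, y, equal_var=False)
            assert gotw.statistic == pytest.approx(refw.statistic, rel=1e-10)
            assert gotw.p_value == pytest.approx(refw.pvalue, rel=1e-10)

    def test_identical_constant_groups(self):
        r = two_sample_t([5.0, 5.0, 5.0], [5.0, 5.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


def _recs(times_events, group):
    return [
        SurvivalRecord(f"{group}{i}", t, e, group)
        for i, (t, e) in enumerate(times_events)
    ]


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        times = np.round(rng.exponential(10, size=60) + 0.5, 2)
        recs = _recs([(t, True) for t in times], "g")
        curve = kaplan_meier(recs)["g"]
        for t, s in zip(curve.times, curve.survival):
            ecdf = (times <= t).mean()
            assert s == pytest.approx(1.0 - ecdf, abs=1e-12)

    def test_censored_subject_at_tied_time_stays_at_risk(self):
        recs = _recs([(2.0, True), (2.0, False), (5.0, True)], "g")
        curve = kaplan_meier(recs)["g"]
        # at t=2 all 3 at risk -> S=2/3; at t=5 one left -> S=0
        assert curve.n_risk == (3, 1)
        assert curve.survival == pytest.approx((2 / 3, 0.0))

    def test_matches_lifelines_with_random_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(29)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            times = np.round(rng.exponential(8, size=n), 1) + 0.1
            events = rng.random(n) < 0.7
            recs = _recs(list(zip(times, events)), "g")
            curve = kaplan_meier(recs)["g"]
            kmf = lifelines.KaplanMeierFitter().fit(times, events)
            for t, s in zip(curve.times, curve.survival):
                ref = float(kmf.survival_function_at_times(t).iloc[0])
                assert s == pytest.approx(ref, abs=1e-8)

    def test_at_is_right_continuous_step(self):
        curve = KMCurve("g", (1.0, 3.0), (4, 2), (1, 1), (0.75, 0.375))
        assert curve.at(0.5) == 1.0
        assert curve.at(1.0) == 0.75
        assert curve.at(2.9) == 0.75
        assert curve.at(3.0) == 0.375
        assert curve.at(100.0) == 0.375


class TestLogRank:
    def test_hand_computed_six_subject_example(self):
        # group a: events at 1, 3; censored at 4.  group b: events at 2, 4, 5.
        recs = _recs([(1.0, True), (3.0, True), (4.0, False)], "a") + _recs(
            [(2.0, True), (4.0, True), (5.0, True)], "b"
        )
        # time 1: n=6, n_a=3, d=1, d_a=1 -> O-E += 1 - 1/2, V += (1/2)(1/2)
        # time 2: n=5, n_a=2, d=1, d_a=0 -> O-E += -2/5, V += (2/5)(3/5)
        # time 3: n=4, n_a=2, d=1, d_a=1 -> O-E += 1/2, V += 1/4
        # time 4: n=3, n_a=1, d=1, d_a=0 -> O-E += -1/3, V += (1/3)(2/3)
        # time 5: n=1, d=1 -> no variance contribution (n=1)
        ome = 0.5 - 0.4 + 0.5 - 1 / 3
        var = 0.25 + 0.24 + 0.25 + 2 / 9
        r = log_rank(recs)
        assert r.statistic == pytest.approx(ome**2 / var, rel=1e-12)
        from scipy.stats import chi2

        assert r.p_value == pytest.approx(chi2.sf(r.statistic, 1), rel=1e-10)

    def test_identical_groups_give_p_one(self):
        base = [(1.0, True), (2.5, True), (4.0, False), (6.0, True)]
        recs = _recs(base, "a") + _recs(base, "b")
        r = log_rank(recs)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(71)
        for _ in range(50):
            n1, n2 = int(rng.integers(4, 40)), int(rng.integers(4, 40))
            t1 = np.round(rng.exponential(8, size=n1), 1) + 0.1
            t2 = np.round(rng.exponential(5, size=n2), 1) + 0.1
            e1 = rng.random(n1) < 0.8
            e2 = rng.random(n2) < 0.8
            if not (e1.any() or e2.any()):
                continue
            recs = _recs(list(zip(t1, e1)), "a") + _recs(list(zip(t2, e2)), "b")
            got = log_rank(recs)
            ref = lifelines_stats.logrank_test(t1, t2, e1, e2)
            assert got.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
            assert got.p_value == pytest.approx(ref.p_value, rel=1e-8)

    def test_requires_two_groups_and_events(self):
        with pytest.raises(ValueError, match="two groups"):
            log_rank(_recs([(1.0, True)], "a"))
        with pytest.raises(ValueError, match="no events"):
            log_rank(_recs([(1.0, False)], "a") + _recs([(2.0, False)], "b"))
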