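"""Stats tests, checked against independent enumeration oracles.

The oracles below use plain itertools loops over every within-block
ordering (or every group labeling for the two-sample test) and share no
code with the implementations they check.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from groundflow.stats import (
    FriedmanResult,
    PairwiseTestResult,
    friedman_allpairs_exact,
    friedman_test,
    mann_whitney,
    results_to_frame,
    results_to_table,
    type_one_error_sim,
)


# ---------------------------------------------------------------- oracles
def oracle_friedman_exact_p(matrix):
    """P(statistic >= observed) by looping over all (k!)^n orderings."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = [tuple(sps.rankdata(row)) for row in matrix]

    def statistic(colsums):
        dev = [c - n * (k + 1) / 2 for c in colsums]
        return 12.0 * sum(d * d for d in dev) / (n * k * (k + 1))

    obs = statistic([sum(r[j] for r in ranks) for j in range(k)])
    hits = total = 0
    for arrangement in itertools.product(*(itertools.permutations(r) for r in ranks)):
        colsums = [sum(row[j] for row in arrangement) for j in range(k)]
        if statistic(colsums) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def oracle_allpairs_exact_p(matrix, j, jp):
    """P(|R_j - R_j'| >= observed) by the same exhaustive loop."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = [tuple(sps.rankdata(row)) for row in matrix]
    obs = abs(
        sum(r[j] for r in ranks) - sum(r[jp] for r in ranks)
    )
    hits = total = 0
    for arrangement in itertools.product(*(itertools.permutations(r) for r in ranks)):
        d = abs(sum(row[j] for row in arrangement) - sum(row[jp] for row in arrangement))
        if d >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def oracle_mann_whitney_p(xs, ys):
    """Two-sided exact p by looping over every group labeling."""
    xs, ys = list(xs), list(ys)
    pooled = xs + ys
    n1 = len(xs)

    def u_of(sample, other):
        return sum(1.0 for a in sample for b in other if a > b) + 0.5 * sum(
            1.0 for a in sample for b in other if a == b
        )

    mean_u = n1 * len(ys) / 2.0
    obs = abs(u_of(xs, ys) - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        group = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_of(group, rest) - mean_u) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------- friedman
class TestFriedmanTest:
    def test_identical_columns(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 4))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_fully_concordant_3x3(self):
        m = np.array([[1.0, 2.0, 3.0]] * 3) + np.arange(3)[:, None] * 10
        res = friedman_test(m)
        assert res.statistic == pytest.approx(6.0)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(6 / 216)

    def test_statistic_matches_scipy(self, rng):
        m = rng.normal(size=(12, 5))
        res = friedman_test(m)
        stat, _ = sps.friedmanchisquare(*m.T)
        assert res.statistic == pytest.approx(stat)

    def test_exact_p_matches_oracle(self, rng):
        for _ in range(5):
            m = rng.normal(size=(3, 3))
            res = friedman_test(m)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(oracle_friedman_exact_p(m))

    def test_chi2_close_to_exact_for_moderate_n(self, rng):
        # blocks are iid, so the exact distribution factorizes over
        # blocks; dynamic programming over column-sum states gives the
        # oracle without touching the 6^10 orderings directly
        n, k = 10, 3
        m = rng.normal(size=(n, k))
        # relative accuracy is only meaningful away from the far tail;
        # redraw until the instance lands in the mid-range
        while sps.friedmanchisquare(*m.T).pvalue < 0.05:
            m = rng.normal(size=(n, k))
        ranks = np.vstack([sps.rankdata(r) for r in m])
        perms = list(itertools.permutations(range(k)))
        dist = {(0.0, 0.0, 0.0): 1.0}
        for row in ranks:
            new = {}
            for state, cnt in dist.items():
                for p in perms:
                    key = tuple(s + row[j] for s, j in zip(state, p))
                    new[key] = new.get(key, 0.0) + cnt
            dist = new

        def statistic(colsums):
            dev = [c - n * (k + 1) / 2 for c in colsums]
            return 12.0 * sum(d * d for d in dev) / (n * k * (k + 1))

        obs = statistic(ranks.sum(axis=0))
        total = sum(dist.values())
        exact_p = sum(c for s, c in dist.items() if statistic(s) >= obs - 1e-12) / total

        res = friedman_test(m)
        assert res.method == "chi2"
        # the chi-square approximation at this size is good to ~20% in
        # the mid-range (worse in the far tail)
        assert res.pvalue == pytest.approx(exact_p, rel=0.25)

    def test_missing_cells_rejected(self):
        m = np.ones((3, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(m)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))


# ---------------------------------------------------------------- all-pairs
class TestFriedmanAllPairs:
    def test_identical_columns_all_p_one(self):
        m = np.tile(np.arange(4.0)[:, None], (1, 3))
        results = friedman_allpairs_exact(m)
        assert all(r.pvalue_adjusted == 1.0 for r in results)

    def test_symmetry_under_column_swap(self, rng):
        m = rng.normal(size=(4, 3))
        a = friedman_allpairs_exact(m)
        swapped = m[:, [1, 0, 2]]
        b = friedman_allpairs_exact(swapped)
        assert a[0].pvalue == pytest.approx(b[0].pvalue)

    def test_maximally_separated_pair_matches_oracle(self):
        # every block ranks column 2 top and column 0 bottom
        m = np.array([[0.0, 1.0, 2.0]] * 4) + np.arange(4)[:, None]
        results = friedman_allpairs_exact(m, adjust="none")
        r02 = next(r for r in results if r.pair == ("0", "2"))
        assert r02.method == "exact"
        assert r02.pvalue == pytest.approx(oracle_allpairs_exact_p(m, 0, 2))

    def test_random_instances_match_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(2, 5))
            k = int(rng.integers(2, 5))
            m = rng.normal(size=(n, k))
            results = friedman_allpairs_exact(m, adjust="none")
            for r in results:
                j, jp = int(r.pair[0]), int(r.pair[1])
                assert r.pvalue == pytest.approx(oracle_allpairs_exact_p(m, j, jp)), (n, k)

    def test_adjustment_caps_at_one(self, rng):
        m = rng.normal(size=(3, 4))
        results = friedman_allpairs_exact(m, adjust="bonferroni")
        for r in results:
            assert r.pvalue <= r.pvalue_adjusted <= 1.0

    def test_holm_not_larger_than_bonferroni(self, rng):
        m = rng.normal(size=(4, 4))
        bonf = friedman_allpairs_exact(m, adjust="bonferroni")
        holm = friedman_allpairs_exact(m, adjust="holm")
        for b, h in zip(bonf, holm):
            assert h.pvalue_adjusted <= b.pvalue_adjusted + 1e-12

    def test_monotonicity_in_separation(self, rng):
        # when a column already dominates another elementwise, raising it
        # further can only (weakly) strengthen the evidence against it
        base = rng.normal(size=(6, 3))
        base[:, 0] = base.max(axis=1) + rng.uniform(0.0, 0.5, size=6)
        p_before = friedman_allpairs_exact(base, adjust="none")[0].pvalue  # pair (0,1)
        shifted = base.copy()
        shifted[:, 0] += 5.0
        p_after = friedman_allpairs_exact(shifted, adjust="none")[0].pvalue
        assert p_after <= p_before + 1e-12

    def test_mc_fallback_used_for_large_instances(self, rng):
        m = rng.normal(size=(10, 6))
        results = friedman_allpairs_exact(m, n_mc=2000, seed=5)
        assert results[0].method == "mc:2000"
        assert len(results) == 15

    def test_mc_close_to_exact_on_feasible_instance(self, rng):
        m = rng.normal(size=(4, 3))
        exact = friedman_allpairs_exact(m, adjust="none")
        mc = friedman_allpairs_exact(m, adjust="none", n_mc=40000, seed=3)
        # force the MC path by shrinking the exact budget
        import groundflow.stats as gstats

        old = gstats.MAX_EXACT
        gstats.MAX_EXACT = 10
        try:
            mc = friedman_allpairs_exact(m, adjust="none", n_mc=40000, seed=3)
        finally:
            gstats.MAX_EXACT = old
        for e, s in zip(exact, mc):
            assert s.pvalue == pytest.approx(e.pvalue, abs=0.02)


# ---------------------------------------------------------------- mann-whitney
class TestMannWhitney:
    def test_separated_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_u_identity(self, rng):
        xs = rng.normal(size=6)
        ys = rng.normal(size=8)
        ux, _ = mann_whitney(xs, ys)
        uy, _ = mann_whitney(ys, xs)
        assert ux + uy == pytest.approx(48.0)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_matches_oracle(self, rng):
        for _ in range(10):
            xs = rng.normal(size=int(rng.integers(2, 5)))
            ys = rng.normal(size=int(rng.integers(2, 5)))
            _, p = mann_whitney(xs, ys)
            assert p == pytest.approx(oracle_mann_whitney_p(xs, ys))

    def test_exact_matches_scipy(self, rng):
        xs = rng.normal(size=5)
        ys = rng.normal(size=6)
        _, p = mann_whitney(xs, ys)
        ref = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_approx_matches_scipy_with_ties(self, rng):
        xs = np.round(rng.normal(size=30), 1)
        ys = np.round(rng.normal(size=25), 1)
        _, p = mann_whitney(xs, ys, exact=False)
        ref = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0, 1.0], [2.0, 3.0], exact=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------- harness
class TestTypeOneErrorSim:
    def test_alpha_one_always_rejects(self):
        rate = type_one_error_sim(lambda r: r.normal(size=(5, 3)), alpha=1.0, reps=100, seed=0)
        assert rate == 1.0

    def test_deterministic_under_seed(self):
        gen = lambda r: r.normal(size=(8, 4))
        a = type_one_error_sim(gen, alpha=0.05, reps=150, seed=9)
        b = type_one_error_sim(gen, alpha=0.05, reps=150, seed=9)
        assert a == b

    def test_minimum_reps_enforced(self):
        with pytest.raises(ValueError):
            type_one_error_sim(lambda r: r.normal(size=(5, 3)), reps=10)


# ---------------------------------------------------------------- exports
class TestResultExport:
    def test_frame_and_table(self, rng):
        m = rng.normal(size=(4, 3))
        results = friedman_allpairs_exact(m)
        df = results_to_frame(results)
        assert set(df.columns) >= {"treatment_a", "treatment_b", "statistic", "pvalue", "pvalue_adjusted"}
        table = results_to_table(results)
        assert table.shape == (3, 3)
        # lower triangle filled, diagonal empty
        assert np.isnan(table.iloc[0, 0])
        assert not np.isnan(table.iloc[2, 0])

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            PairwiseTestResult(pair=("a", "b"), statistic=1.0, pvalue=0.5, pvalue_adjusted=0.4, method="exact")
        with pytest.raises(ValueError):
            PairwiseTestResult(pair=("a", "b"), statistic=1.0, pvalue=0.0, pvalue_adjusted=0.0, method="exact")
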