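"""Nonparametric tests with enumeration-exact small-sample nulls.

Friedman omnibus test over flights-by-bins matrices, exact all-pairs
rank-sum comparisons between bins as the post hoc, and Mann–Whitney
for between-condition comparisons.  Whenever the permutation space is
small enough the null distribution is enumerated exhaustively (every
within-block ordering, every group labeling); otherwise a chi-square
approximation (omnibus), seeded Monte-Carlo permutations (all-pairs),
or a tie-corrected normal approximation (Mann–Whitney) is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import EpochMatrix

__all__ = [
    "FriedmanResult",
    "PairwiseTestResult",
    "friedman_test",
    "friedman_allpairs_exact",
    "mann_whitney",
    "type_one_error_sim",
    "results_to_frame",
    "results_to_table",
]

#: exhaustive enumeration is used when the permutation space is at most this big
MAX_EXACT = 1_000_000


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float
    method: str  # "exact" or "chi2"
    n_blocks: int
    n_treatments: int


@dataclass(frozen=True)
class PairwiseTestResult:
    """One post hoc comparison between two treatments (bins)."""

    pair: tuple
    statistic: float
    pvalue: float
    pvalue_adjusted: float
    method: str

    def __post_init__(self) -> None:
        for p in (self.pvalue, self.pvalue_adjusted):
            if not 0.0 < p <= 1.0:
                raise ValueError(f"p-value out of (0, 1]: {p}")
        if self.pvalue_adjusted < self.pvalue:
            raise ValueError("adjusted p cannot be smaller than the raw p")


def _as_matrix(matrix) -> tuple[np.ndarray, list]:
    """Accept an EpochMatrix or a plain 2-D array; return values + labels."""
    if isinstance(matrix, EpochMatrix):
        return matrix.values, [f"{c:.3g}" for c in matrix.bin_centers]
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    return arr, [str(j) for j in range(arr.shape[1])]


def _validate(values: np.ndarray) -> None:
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing cells are not allowed")


def _within_block_ranks(values: np.ndarray) -> np.ndarray:
    return np.vstack([sps.rankdata(row) for row in values])


def _tie_term(ranks: np.ndarray) -> float:
    """Sum over blocks of sum(t^3 - t) over tied groups."""
    total = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        total += float(np.sum(counts.astype(float) ** 3 - counts))
    return total


def _friedman_statistic(colsums: np.ndarray, n: int, k: int, tie_term: float) -> np.ndarray:
    """Tie-corrected Friedman chi-square from column rank sums."""
    denom = n * k * (k + 1) - tie_term / (k - 1)
    dev = colsums - n * (k + 1) / 2.0
    num = 12.0 * np.sum(np.square(dev), axis=-1)
    if denom <= 0:  # every block entirely tied
        return np.zeros(np.shape(num))
    return num / denom


def _enumerate_colsums(ranks: np.ndarray) -> np.ndarray:
    """Column rank-sum of every within-block ordering, shape ((k!)^n, k).

    Each block's observed (mid)rank vector is permuted through all k!
    arrangements; blocks combine independently.
    """
    n, k = ranks.shape
    perms = np.array(list(itertools.permutations(range(k))))  # (k!, k)
    acc = np.zeros((1, k))
    for row in ranks:
        block = row[perms]  # (k!, k)
        acc = (acc[:, None, :] + block[None, :, :]).reshape(-1, k)
    return acc


def _exact_space(n: int, k: int) -> float:
    return float(math.factorial(k)) ** n


def friedman_test(matrix) -> FriedmanResult:
    """Friedman rank test over a blocks-by-treatments matrix.

    Within-block midranks, tie-corrected chi-square statistic; the
    p-value is exact (full enumeration of within-block orderings) when
    the permutation space does not exceed ``MAX_EXACT``, otherwise the
    chi-square approximation with k-1 degrees of freedom.
    """
    values, _ = _as_matrix(matrix)
    _validate(values)
    n, k = values.shape
    ranks = _within_block_ranks(values)
    tie = _tie_term(ranks)
    observed = float(_friedman_statistic(ranks.sum(axis=0), n, k, tie))

    if _exact_space(n, k) <= MAX_EXACT:
        colsums = _enumerate_colsums(ranks)
        null = _friedman_statistic(colsums, n, k, tie)
        p = float(np.mean(null >= observed - 1e-12))
        return FriedmanResult(observed, p, "exact", n, k)
    p = float(sps.chi2.sf(observed, df=k - 1))
    return FriedmanResult(observed, min(1.0, max(p, np.finfo(float).tiny)), "chi2", n, k)


def _adjust(pvalues: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment method {method!r}")


def friedman_allpairs_exact(
    matrix,
    adjust: str = "bonferroni",
    n_mc: int = 100_000,
    seed: int = 0,
) -> list[PairwiseTestResult]:
    """All-pairs comparisons between treatments after a Friedman omnibus.

    For each treatment pair the statistic is the absolute difference of
    within-block rank sums; its null distribution comes from permuting
    each block's ranks independently — exhaustively when the space is
    at most ``MAX_EXACT`` orderings, otherwise by ``n_mc`` seeded
    Monte-Carlo draws.  Two-sided p = P(D* >= D observed), then
    adjusted for multiplicity (Bonferroni by default, capped at 1).
    """
    values, labels = _as_matrix(matrix)
    _validate(values)
    n, k = values.shape
    if n_mc < 1:
        raise ValueError("n_mc must be positive")
    ranks = _within_block_ranks(values)
    obs_colsums = ranks.sum(axis=0)

    if _exact_space(n, k) <= MAX_EXACT:
        null_colsums = _enumerate_colsums(ranks)
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        # independent within-row permutations, vectorized over draws
        null_colsums = np.zeros((n_mc, k))
        for i in range(n):
            idx = np.argsort(rng.random((n_mc, k)), axis=1)
            null_colsums += ranks[i][idx]
        method = f"mc:{n_mc}"

    results = []
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    stats = []
    for j, jp in pairs:
        d_obs = abs(obs_colsums[j] - obs_colsums[jp])
        d_null = np.abs(null_colsums[:, j] - null_colsums[:, jp])
        hits = int(np.sum(d_null >= d_obs - 1e-12))
        if method == "exact":
            raw.append(hits / null_colsums.shape[0])
        else:  # add-one so a Monte-Carlo p can never be 0
            raw.append((hits + 1) / (null_colsums.shape[0] + 1))
        stats.append(float(d_obs))
    adj = _adjust(np.array(raw), adjust)
    for (j, jp), d, p, pa in zip(pairs, stats, raw, adj):
        results.append(
            PairwiseTestResult(
                pair=(labels[j], labels[jp]),
                statistic=d,
                pvalue=p,
                pvalue_adjusted=float(pa),
                method=method,
            )
        )
    return results


def mann_whitney(xs, ys, exact: bool | None = None) -> tuple[float, float]:
    """Mann–Whitney U with enumeration-exact p for small untied samples.

    Returns ``(U, p)`` where U counts (x, y) pairs with x > y (ties
    count half) and p is two-sided.  ``exact=None`` chooses enumeration
    whenever there are no ties and the labeling space is at most
    ``MAX_EXACT``; the fallback is the tie- and continuity-corrected
    normal approximation.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xs.size, ys.size
    pooled = np.concatenate([xs, ys])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0  # pairs with x > y, ties half

    has_ties = np.unique(pooled).size < pooled.size
    space = math.comb(n1 + n2, n1)
    if exact is None:
        exact = (not has_ties) and space <= MAX_EXACT
    if exact and has_ties:
        raise ValueError("exact enumeration requires tie-free samples")
    if exact and space > MAX_EXACT:
        raise ValueError(f"labeling space {space} too large for exact enumeration")

    if exact:
        mean_u = n1 * n2 / 2.0
        dev = abs(u - mean_u)
        order = np.argsort(pooled)
        # rank of each pooled position (no ties, so 1..N)
        pos_ranks = np.empty(n1 + n2)
        pos_ranks[order] = np.arange(1, n1 + n2 + 1)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            r = pos_ranks[list(combo)].sum()
            u_star = r - n1 * (n1 + 1) / 2.0
            if abs(u_star - mean_u) >= dev - 1e-12:
                count += 1
            total += 1
        return u, count / total

    # normal approximation with tie and continuity corrections
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts.astype(float) ** 3 - counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var_u <= 0:
        return u, 1.0
    zval = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    p = 2.0 * sps.norm.sf(max(zval, 0.0))
    return u, float(min(1.0, p))


def type_one_error_sim(null_generator, alpha: float = 0.01, reps: int = 1000, seed: int = 0) -> float:
    """Empirical rejection rate of the Friedman omnibus under a null.

    ``null_generator(rng)`` must return one blocks-by-treatments matrix
    (or EpochMatrix) drawn from a no-effect model.  Returns the
    fraction of ``reps`` replicates with omnibus p < ``alpha``;
    deterministic for a fixed seed.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        matrix = null_generator(rng)
        if friedman_test(matrix).pvalue <= alpha:
            rejections += 1
    return rejections / reps


def results_to_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    """Tabulate pairwise results (pair, statistic, p, adjusted p)."""
    return pd.DataFrame(
        {
            "treatment_a": [r.pair[0] for r in results],
            "treatment_b": [r.pair[1] for r in results],
            "statistic": [r.statistic for r in results],
            "pvalue": [r.pvalue for r in results],
            "pvalue_adjusted": [r.pvalue_adjusted for r in results],
            "method": [r.method for r in results],
        }
    )


def results_to_table(results: list[PairwiseTestResult]) -> pd.DataFrame:
    """Lower-triangular matrix of adjusted p-values, labels on both axes."""
    labels: list = []
    for r in results:
        for lab in r.pair:
            if lab not in labels:
                labels.append(lab)
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for r in results:
        a, b = r.pair
        i, j = labels.index(a), labels.index(b)
        if i < j:
            table.iloc[j, i] = r.pvalue_adjusted
        else:
            table.iloc[i, j] = r.pvalue_adjusted
    return table
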