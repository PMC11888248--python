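"""Statistical primitives shared by every pipeline stage.

AUROC is the mid-rank Mann-Whitney statistic; enrichment tests are the
hypergeometric upper tail and Fisher's exact test; the rank-sum test is exact
by enumeration for small samples and normal-approximated (with tie
correction) otherwise; empirical permutation p-values carry the +1
correction so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._util import substream


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    tail: str
    n: tuple = ()
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def auroc(scores, positives) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape:
        raise ValueError("scores and positives must have equal length")
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = sps.rankdata(scores)
    r_pos = ranks[positives].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks); NaN if a vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, tail: str) -> float:
    """Exact rank-sum p over all equally likely assignments of the combined ranks.

    Dynamic-programming convolution on doubled mid-ranks (integers even under
    ties), so the null distribution conditions on the observed tie pattern.
    """
    ranks = sps.rankdata(np.concatenate([x, y]))
    n = ranks.size
    nx = x.size
    r2 = np.rint(2 * ranks).astype(np.int64)
    w_obs2 = int(np.rint(2 * ranks[:nx].sum()))
    mean2 = nx * (n + 1)  # doubled null mean of the rank sum
    max_w = int(r2.sum())
    dp = np.zeros((nx + 1, max_w + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for j in range(nx, 0, -1):
            dp[j, r:] += dp[j - 1, : max_w + 1 - r]
    dist = dp[nx]
    total = dist.sum()
    w = np.arange(max_w + 1)
    if tail == "greater":
        count = dist[w >= w_obs2].sum()
    elif tail == "less":
        count = dist[w <= w_obs2].sum()
    else:
        dev = abs(w_obs2 - mean2)
        count = dist[np.abs(w - mean2) >= dev].sum()
    return float(count / total)


def rank_sum_test(x, y, tail: str = "two-sided", exact_below_n: int = 20) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact (tie-conditioned) null distribution when the combined sample is
    below ``exact_below_n``; normal approximation with tie correction
    otherwise. The exact path scales to ~100 combined observations if asked.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    u = sps.mannwhitneyu(x, y, alternative=alt, method="asymptotic").statistic
    if x.size + y.size < exact_below_n:
        p = _exact_rank_sum_p(x, y, tail)
        method = "rank-sum (exact)"
    else:
        p = float(sps.mannwhitneyu(x, y, alternative=alt, method="asymptotic").pvalue)
        method = "rank-sum (normal approx.)"
    return TestResult(float(u), min(1.0, p), method, tail, (x.size, y.size))


def hypergeom_overlap_test(k: int, n_a: int, n_b: int, universe: int) -> TestResult:
    """Upper-tail P(X >= k) for the overlap of two sets drawn from a universe."""
    if not (0 <= k <= min(n_a, n_b) <= universe):
        raise ValueError(f"infeasible margins k={k}, nA={n_a}, nB={n_b}, N={universe}")
    p = float(sps.hypergeom.sf(k - 1, universe, n_a, n_b))
    return TestResult(float(k), min(1.0, p), "hypergeometric overlap", "greater", (n_a, n_b, universe))


def fisher_exact_2x2(table, tail: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table; odds ratio is ad/bc (inf/0 conventions)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.fisher_exact(t, alternative=alt)
    a, b, c, d = t.ravel()
    if b * c == 0:
        oddsratio = float("inf") if a * d > 0 else (0.0 if a * d == 0 and (b > 0 or c > 0) else float("nan"))
    else:
        oddsratio = float(a * d) / float(b * c)
    return TestResult(oddsratio, float(res.pvalue), "fisher exact", tail, tuple(t.ravel()))


def adjust_p(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' or 'bh' (Benjamini-Hochberg)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


def permutation_overlap_test(
    sets: list[set], universe: set, n_perm: int = 2000, seed: int = 0, tail: str = "less"
) -> TestResult:
    """Permutation test for the size of the common intersection of several sets.

    Each replicate redraws every set as a uniform random subset of the universe
    of the same size; the statistic is the size of the intersection of all
    sets. The empirical p uses the +1 correction. ``extra['expected']`` holds
    the permutation mean.
    """
    universe_arr = np.array(sorted(universe), dtype=object)
    sizes = [len(s) for s in sets]
    for s in sets:
        if not set(s) <= set(universe):
            raise ValueError("every set must be a subset of the universe")
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    observed = len(set.intersection(*[set(s) for s in sets])) if sets else 0
    if len(sets) <= 1:
        exp = float(sizes[0]) if sets else 0.0
        return TestResult(float(observed), 1.0, "permutation overlap", tail,
                          (len(sets), n_perm), {"expected": exp})
    rng = substream(seed, "permutation_overlap")
    n_u = universe_arr.size
    stats = np.empty(n_perm)
    for i in range(n_perm):
        inter = None
        for sz in sizes:
            draw = set(rng.choice(n_u, size=sz, replace=False))
            inter = draw if inter is None else (inter & draw)
            if not inter:
                break
        stats[i] = 0 if not inter else len(inter)
    if tail == "less":
        extreme = np.sum(stats <= observed)
    elif tail == "greater":
        extreme = np.sum(stats >= observed)
    else:
        dev = abs(observed - stats.mean())
        extreme = np.sum(np.abs(stats - stats.mean()) >= dev - 1e-12)
    p = float((1 + extreme) / (n_perm + 1))
    return TestResult(
        float(observed), min(1.0, p), "permutation overlap", tail,
        (len(sets), n_perm), {"expected": float(stats.mean())},
    )
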