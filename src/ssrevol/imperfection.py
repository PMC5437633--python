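"""Mismatch-by-length frequency datasets and their relationship analyses.

The genomic abundance of imperfect microsatellites is summarized as
frequency matrices (genomes x (repeat length, mismatch count) cells) and
interrogated four ways:

* :func:`build_datasets` — dataset I counts loci of length 20-24 nt with
  0 or 1 mismatch, dataset II counts loci of length 25-29 nt with 1 or 2
  mismatches; loci shorter than 20 nt are excluded outright (they carry no
  mismatch).
* :func:`canonical_ordination` — principal coordinates of two blocks
  (Euclidean distances on raw counts), retaining axes that explain >= 95%
  of the variation, followed by the first squared canonical correlation
  between the two axis sets; significance by row permutation with the
  add-one rule, so p >= 1/(n_permutations + 1).
* :func:`permanova` — permutational multivariate ANOVA with the pseudo-F
  statistic in its Gower-centred trace form, sequential sums of squares
  (factors enter in the order given), permutation p-values; small instances
  can be enumerated exhaustively.
* :func:`pairwise_length_correlations` and
  :func:`regress_mismatch_on_length` — Pearson correlations between
  mismatch levels across genomes at fixed repeat length, and OLS of
  per-motif-class mean mismatch on mean repeat length.

The Euclidean distance on raw counts is pinned as the default metric
(Bray-Curtis available as an option).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import MicrosatelliteLocus

__all__ = [
    "PermutationTestResult",
    "RegressionFit",
    "build_datasets",
    "canonical_ordination",
    "permanova",
    "pairwise_length_correlations",
    "regress_mismatch_on_length",
]


@dataclass
class PermutationTestResult:
    statistic: float
    statistic_name: str
    p_value: float
    n_permutations: int
    degenerate: bool = False


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def build_datasets(loci_by_genome: Mapping[str, Sequence[MicrosatelliteLocus]]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(dataset I, dataset II) frequency matrices.

    Rows are genomes; columns are ``(repeat_length, mismatch_count)`` pairs:
    lengths 20-24 x mismatch {0, 1} for dataset I and lengths 25-29 x
    mismatch {1, 2} for dataset II.
    """
    genomes = list(loci_by_genome)
    cols_1 = [(L, m) for L in range(20, 25) for m in (0, 1)]
    cols_2 = [(L, m) for L in range(25, 30) for m in (1, 2)]

    def count(cells):
        data = np.zeros((len(genomes), len(cells)), dtype=int)
        index = {c: j for j, c in enumerate(cells)}
        for i, g in enumerate(genomes):
            for loc in loci_by_genome[g]:
                key = (loc.repeat_length, loc.mismatch_count)
                if key in index:
                    data[i, index[key]] += 1
        return pd.DataFrame(
            data, index=pd.Index(genomes, name="genome"),
            columns=pd.MultiIndex.from_tuples(
                cells, names=["repeat_length", "mismatch_count"]))

    return count(cols_1), count(cols_2)


def _pcoa_scores(block: np.ndarray, var_threshold: float = 0.95
                 ) -> np.ndarray:
    """Principal coordinate scores (Euclidean metric => centred PCA),
    keeping the fewest axes whose cumulative variance is >= threshold."""
    X = np.asarray(block, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    tot = var.sum()
    if tot <= 0:
        raise ValueError("degenerate block: zero variance")
    keep = int(np.searchsorted(np.cumsum(var) / tot, var_threshold) + 1)
    keep = max(1, min(keep, int((var > tot * 1e-12).sum())))
    return U[:, :keep] * s[:keep]


def _first_sq_canonical_corr(X: np.ndarray, Y: np.ndarray) -> float:
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, _ = np.linalg.qr(Xc)
    Qy, _ = np.linalg.qr(Yc)
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    r = min(1.0, float(s[0]))
    return r * r


def canonical_ordination(matrix_A, matrix_B, n_permutations: int = 9999,
                         seed: int = 0, var_threshold: float = 0.95
                         ) -> tuple[PermutationTestResult, np.ndarray,
                                    np.ndarray]:
    """First squared canonical correlation between the principal-coordinate
    axes of two blocks sharing the same genome rows.

    Returns ``(result, scores_A, scores_B)``.  The permutation null
    shuffles the row order of block B; add-one rule keeps p > 0.
    """
    A = np.asarray(matrix_A, dtype=float)
    B = np.asarray(matrix_B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("blocks must share the same rows")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    SA = _pcoa_scores(A, var_threshold)
    SB = _pcoa_scores(B, var_threshold)
    obs = _first_sq_canonical_corr(SA, SB)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _first_sq_canonical_corr(SA, SB[perm]) >= obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return (PermutationTestResult(obs, "first_squared_canonical_correlation",
                                  p, n_permutations), SA, SB)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ d2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _dummy(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels])


def _squared_distances(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        sq = (X ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
        return np.maximum(d2, 0.0)
    if metric == "braycurtis":
        num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        den = np.abs(X[:, None, :] + X[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            d = np.where(den > 0, num / den, 0.0)
        return d ** 2
    raise ValueError(f"unknown metric {metric!r}")


def permanova(response, factors: Mapping[str, Sequence],
              n_permutations: int | str = 999, seed: int = 0,
              metric: str = "euclidean"
              ) -> dict[str, PermutationTestResult]:
    """Sequential (type-I) PERMANOVA on a multivariate response.

    ``factors`` maps factor name -> per-row categorical labels; terms enter
    the model in mapping order.  The pseudo-F of each term uses the trace
    form on the Gower-centred matrix of squared distances; p-values permute
    the response rows jointly.  ``n_permutations="exhaustive"`` enumerates
    all row permutations (small n only).
    """
    X = np.asarray(response, dtype=float)
    n = X.shape[0]
    names = list(factors)
    labels = {f: np.asarray(factors[f]) for f in names}
    for f in names:
        if len(labels[f]) != n:
            raise ValueError(f"factor {f!r} length mismatch")
        if len(pd.unique(labels[f])) < 2:
            raise ValueError(f"factor {f!r} has a single level")
    d2 = _squared_distances(X, metric)
    G = _gower_center(d2)
    total_ss = float(np.trace(G))
    if total_ss <= 1e-12:
        return {f: PermutationTestResult(float("nan"), "pseudo-F",
                                         float("nan"), 0, degenerate=True)
                for f in names}
    # hat matrices for the nested sequence of models
    designs = []
    cur = [np.ones((n, 1))]
    for f in names:
        cur = cur + [_dummy(labels[f])]
        designs.append(np.column_stack(cur))
    hats = [_hat(D) for D in designs]
    dfs = [np.linalg.matrix_rank(D) for D in designs]
    df_terms = [dfs[0] - 1] + [dfs[i] - dfs[i - 1] for i in range(1, len(dfs))]
    df_res = n - dfs[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def pseudo_f(Gm):
        prev_tr = 0.0
        tot = float(np.trace(Gm))
        ss_terms = []
        for H in hats:
            tr = float(np.trace(H @ Gm))
            ss_terms.append(tr - prev_tr)
            prev_tr = tr
        ss_res = tot - prev_tr
        return [(ss / df) / (ss_res / df_res) if df > 0 else float("nan")
                for ss, df in zip(ss_terms, df_terms)]

    obs = pseudo_f(G)
    if n_permutations == "exhaustive":
        perms = list(itertools.permutations(range(n)))
        counts = [0] * len(names)
        for perm in perms:
            idx = np.array(perm)
            fs = pseudo_f(G[np.ix_(idx, idx)])
            for i in range(len(names)):
                if fs[i] >= obs[i] - 1e-12:
                    counts[i] += 1
        n_perm = len(perms)
        ps = [c / n_perm for c in counts]
    else:
        rng = np.random.default_rng(seed)
        counts = [0] * len(names)
        for _ in range(int(n_permutations)):
            idx = rng.permutation(n)
            fs = pseudo_f(G[np.ix_(idx, idx)])
            for i in range(len(names)):
                if fs[i] >= obs[i]:
                    counts[i] += 1
        n_perm = int(n_permutations)
        ps = [(1 + c) / (n_perm + 1) for c in counts]
    return {f: PermutationTestResult(obs[i], "pseudo-F", ps[i], n_perm)
            for i, f in enumerate(names)}


_DEFAULT_LENGTHS = (30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80)


def pairwise_length_correlations(
        loci_by_genome: Mapping[str, Sequence[MicrosatelliteLocus]],
        lengths: Sequence[int] = _DEFAULT_LENGTHS,
        bin_width: int = 5,
        alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r between mismatch-level frequency vectors across genomes.

    For each target length L, loci with repeat length in ``[L, L+bin_width)``
    are counted per genome at mismatch levels 1-4; r is computed for the
    level pairs (1,2), (1,3) and (2,3) with a two-sided t-based p-value.
    Cells with a constant vector are flagged undefined.
    """
    genomes = list(loci_by_genome)
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    freq = {}
    for m in (1, 2, 3, 4):
        for L in lengths:
            freq[(L, m)] = np.array([
                sum(1 for loc in loci_by_genome[g]
                    if loc.mismatch_count == m
                    and L <= loc.repeat_length < L + bin_width)
                for g in genomes], dtype=float)
    rows = []
    for L in lengths:
        for a, b in ((1, 2), (1, 3), (2, 3)):
            x, y = freq[(L, a)], freq[(L, b)]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"repeat_length": L, "mismatch_a": a,
                             "mismatch_b": b, "r": float("nan"),
                             "p_value": float("nan"), "significant": False,
                             "defined": False})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"repeat_length": L, "mismatch_a": a,
                         "mismatch_b": b, "r": float(r),
                         "p_value": float(p), "significant": bool(p < alpha),
                         "defined": True})
    return pd.DataFrame(rows)


def regress_mismatch_on_length(loci: Sequence[MicrosatelliteLocus]
                               ) -> RegressionFit:
    """OLS of per-standardized-motif mean mismatch on mean repeat length."""
    groups: dict[str, list[MicrosatelliteLocus]] = {}
    for loc in loci:
        groups.setdefault(loc.standardized_motif, []).append(loc)
    if len(groups) < 3:
        raise ValueError("need at least 3 motif classes")
    xs = np.array([np.mean([l.repeat_length for l in g])
                   for g in groups.values()])
    ys = np.array([np.mean([l.mismatch_count for l in g])
                   for g in groups.values()])
    if np.ptp(ys) == 0:
        return RegressionFit(0.0, float(ys[0]), 0.0, 1.0, len(groups))
    res = stats.linregress(xs, ys)
    return RegressionFit(float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2), float(res.pvalue),
                         len(groups))
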