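"""Pairwise signature correlation, block summaries, group tests and PCA.

Signatures are compared as whole patterns with Spearman's rank correlation.
The default subset policy takes the union of the two supports with zero
fill, so non-overlap between signatures is penalized rather than ignored;
intersection is available for sensitivity analysis.  Correlation-matrix
regions ("blocks") are summarized as the mean of all unique pairwise
coefficients and the population standard deviation from this mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

EXACT_P_MAX_N = 10  # exact permutation p for n at or below this, t approximation above


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    policy: str


@dataclass
class BlockStat:
    mean: float
    sd: float  # population SD of the pairwise coefficients
    n_pairs: int
    values: np.ndarray


@dataclass
class BlockSummary:
    rho: pd.DataFrame  # symmetric, unit diagonal
    n: pd.DataFrame
    policy: str
    blocks: dict[tuple[str, str], BlockStat] | None = None


def _restrict(x: pd.Series, y: pd.Series, policy: str) -> tuple[np.ndarray, np.ndarray]:
    if not x.index.equals(y.index):
        common = x.index.union(y.index)
        x = x.reindex(common, fill_value=0.0)
        y = y.reindex(common, fill_value=0.0)
    xv, yv = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    if policy == "union":
        keep = (xv != 0) | (yv != 0)
    elif policy == "intersection":
        keep = (xv != 0) & (yv != 0)
    else:
        raise ContractError(f"unknown subset policy {policy!r}")
    return xv[keep], yv[keep]


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxd = rx - rx.mean()
    ryd = ry - ry.mean()
    denom = np.sqrt((rxd @ rxd) * (ryd @ ryd))
    if denom == 0:
        return float("nan")
    return float((rxd @ ryd) / denom)


def spearman(
    x: pd.Series, y: pd.Series, policy: str = "union", p_method: str = "auto"
) -> CorrelationResult:
    """Spearman correlation of two signatures under a subset policy.

    Ranks use average tie handling; rho is Pearson on the ranks.  The
    two-sided p-value is an exact permutation enumeration for n <= 10 and
    the t approximation above (``p_method`` forces one or skips p with
    ``"none"``).  Zero rank variance yields rho = NaN.
    """
    xv, yv = _restrict(x, y, policy)
    n = xv.size
    if n < 3:
        raise ContractError(f"need >= 3 paired observations after {policy} policy (got {n})")
    rx, ry = _rank(xv), _rank(yv)
    rho = _pearson_on_ranks(rx, ry)
    if np.isnan(rho) or p_method == "none":
        return CorrelationResult(rho=rho, p_value=float("nan"), n=n, policy=policy)
    if p_method == "auto":
        p_method = "exact" if n <= EXACT_P_MAX_N else "approx"
    if p_method == "exact":
        perms = _perm_matrix(n)
        ryp = ry[perms]  # all permutations of the y ranks
        rxd = rx - rx.mean()
        ryd = ryp - ry.mean()
        num = ryd @ rxd
        denom = np.sqrt((rxd @ rxd) * np.einsum("ij,ij->i", ryd, ryd))
        rhos = num / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif p_method == "approx":
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    else:
        raise ContractError(f"unknown p_method {p_method!r}")
    return CorrelationResult(rho=rho, p_value=p, n=n, policy=policy)


def correlation_matrix(
    columns, policy: str = "union", p_method: str = "approx"
) -> BlockSummary:
    """Symmetric Spearman matrix over the columns of a fraction table
    (accepts a DataFrame or a FractionMatrix)."""
    if hasattr(columns, "table"):
        columns = columns.table
    ids = list(columns.columns)
    if len(ids) < 2:
        raise ContractError("correlation matrix needs >= 2 samples")
    rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    n = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, a in enumerate(ids):
        n.loc[a, a] = int((columns[a] != 0).sum())
        for b in ids[i + 1 :]:
            res = spearman(columns[a], columns[b], policy=policy, p_method=p_method)
            rho.loc[a, b] = rho.loc[b, a] = res.rho
            n.loc[a, b] = n.loc[b, a] = res.n
    return BlockSummary(rho=rho, n=n, policy=policy)


def block_stats(
    summary: BlockSummary,
    grouping: Mapping[str, str],
    block_pairs: Sequence[tuple[str, str]],
) -> BlockSummary:
    """Mean +/- SD of unique pairwise coefficients for named matrix blocks.

    Within-group blocks (groupA == groupB) run over unordered off-diagonal
    pairs; cross-group blocks over all (a in A, b in B) pairs.
    """
    ids = list(summary.rho.index)
    missing = [s for s in ids if s not in grouping]
    if missing:
        raise ContractError(f"grouping does not cover samples: {missing}")
    blocks: dict[tuple[str, str], BlockStat] = {}
    for ga, gb in block_pairs:
        a_ids = [s for s in ids if grouping[s] == ga]
        b_ids = [s for s in ids if grouping[s] == gb]
        if ga == gb:
            pairs = list(itertools.combinations(a_ids, 2))
        else:
            pairs = [(a, b) for a in a_ids for b in b_ids]
        if not pairs:
            raise ContractError(f"empty correlation block ({ga!r}, {gb!r})")
        vals = np.array([summary.rho.loc[a, b] for a, b in pairs], dtype=float)
        blocks[(ga, gb)] = BlockStat(
            mean=float(vals.mean()), sd=float(vals.std(ddof=0)), n_pairs=len(pairs), values=vals
        )
    return BlockSummary(rho=summary.rho, n=summary.n, policy=summary.policy, blocks=blocks)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def compare_coefficient_groups(
    group_a: Sequence[float], group_b: Sequence[float], test: str = "welch_t"
) -> ComparisonResult:
    """Two-sided comparison of two groups of correlation coefficients."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both coefficient groups must be nonempty")
    if test in ("student_t", "welch_t"):
        if a.size < 2 or b.size < 2:
            raise ContractError("t-tests require >= 2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.allclose(a.mean(), b.mean()):
                return ComparisonResult(test, 0.0, 1.0, float(a.mean()), float(b.mean()))
            raise ContractError("zero variance in both groups with unequal means: t undefined")
        res = stats.ttest_ind(a, b, equal_var=(test == "student_t"))
    elif test == "mann_whitney":
        method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        raise ContractError(f"unknown test {test!r}; use student_t|welch_t|mann_whitney")
    return ComparisonResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    explained_variance: np.ndarray
    explained_ratio: np.ndarray


def pca(fractions, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal components of samples in miRNA space via centered SVD.

    Samples are observations (columns of the fraction table become rows of
    the data matrix), miRNAs are variables.  Defaults (center, no scaling)
    match the usual convention for expression PCA.
    """
    if hasattr(fractions, "table"):
        fractions = fractions.table
    X = fractions.T.to_numpy(dtype=float)  # samples x miRNAs
    n = X.shape[0]
    if n < 2:
        raise ContractError("PCA needs >= 2 samples")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1 if center else n, X.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    scores = U * s
    var = s**2 / (n - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=fractions.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=fractions.index, columns=comp),
        explained_variance=var,
        explained_ratio=ratio,
    )
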