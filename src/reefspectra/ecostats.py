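"""Community-ecology statistics for survey-method comparison.

Implements the rank-based and distance-based statistics used to compare
benthic community estimates between survey methods: Bray-Curtis
dissimilarity, percent community similarity, square-root cover transform,
ANOSIM with permutation (or exact enumeration) significance, non-metric
multidimensional scaling (nMDS, Kruskal stress-1 with isotonic regression),
and one-way ANOVA with Tukey's HSD post-hoc test.

All statistics are computed here directly; scipy is used only for
probability distributions and rank assignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "DissimilarityMatrix",
    "AnosimResult",
    "NmdsResult",
    "AnovaResult",
    "bray_curtis",
    "similarity_percent",
    "sqrt_transform",
    "anosim",
    "nmds",
    "anova_tukey",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if not np.all(np.isfinite(v)):
            raise ValueError("dissimilarities must be finite")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle dissimilarities in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class AnosimResult:
    R: float
    significance: float
    n_permutations: int
    seed: Optional[int]
    method: str = "permutation"
    permutation_Rs: Optional[np.ndarray] = None


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    stress_history: list = field(default_factory=list)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: list  # list of ((group_i, group_j), mean_diff, adjusted_p)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# dissimilarity and transforms
# ---------------------------------------------------------------------------


def bray_curtis(matrix, ids: Optional[Sequence] = None) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity between rows of a cover table.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for identical rows,
    1 for rows with disjoint support.

    Accepts a 2-D array or anything with ``.values``/``.index`` (e.g. a
    pandas DataFrame or a CommunityMatrix).
    """
    if hasattr(matrix, "values") and hasattr(matrix, "index"):
        data = np.asarray(matrix.values, dtype=float)
        if ids is None:
            ids = list(matrix.index)
    else:
        data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if np.any(data < 0):
        raise ValueError("cover values must be nonnegative")
    if ids is None:
        ids = list(range(data.shape[0]))

    diff = np.abs(data[:, None, :] - data[None, :, :]).sum(axis=2)
    tot = (data[:, None, :] + data[None, :, :]).sum(axis=2)
    zero_pairs = tot == 0
    np.fill_diagonal(zero_pairs, False)
    if np.any(zero_pairs):
        i, j = np.argwhere(zero_pairs)[0]
        raise ValueError(
            f"Bray-Curtis undefined for all-zero row pair ({ids[i]}, {ids[j]})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(tot > 0, diff / np.where(tot == 0, 1.0, tot), 0.0)
    np.fill_diagonal(bc, 0.0)
    bc = 0.5 * (bc + bc.T)  # kill fp asymmetry
    return DissimilarityMatrix(list(ids), bc)


def similarity_percent(bc: float) -> float:
    """Percent community similarity: (1 - Bray-Curtis) * 100."""
    if not (0.0 <= bc <= 1.0):
        raise ValueError(f"Bray-Curtis value out of [0, 1]: {bc}")
    return (1.0 - bc) * 100.0


def sqrt_transform(matrix):
    """Element-wise square root of a cover table.

    Used before ordination of high-resolution community data to damp the
    dominance of a few abundant categories. Row sums are no longer 1
    afterwards; callers must treat the result as un-normalized.
    """
    if hasattr(matrix, "values") and hasattr(matrix, "copy"):
        data = np.asarray(matrix.values, dtype=float)
        if np.any(data < 0):
            raise ValueError("cover values must be nonnegative")
        out = matrix.copy()
        try:
            out.values[:] = np.sqrt(data)
            if hasattr(out, "normalized"):
                out.normalized = False
            return out
        except (TypeError, AttributeError):
            pass
        out.loc[:, :] = np.sqrt(data)
        return out
    data = np.asarray(matrix, dtype=float)
    if np.any(data < 0):
        raise ValueError("cover values must be nonnegative")
    return np.sqrt(data)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _anosim_r(rank_matrix: np.ndarray, groups: np.ndarray, m_half: float) -> float:
    within = groups[:, None] == groups[None, :]
    iu = np.triu_indices(len(groups), k=1)
    w = within[iu]
    ranks = rank_matrix[iu]
    return float((ranks[~w].mean() - ranks[w].mean()) / m_half)


def anosim(
    dist: DissimilarityMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> AnosimResult:
    """Analysis of similarities on a ranked dissimilarity matrix.

    Ranks the n(n-1)/2 off-diagonal dissimilarities (average ranks on
    ties) and computes R = (mean between-group rank - mean within-group
    rank) / (M/2), R in [-1, 1]. Significance is the one-sided permutation
    p-value under random relabeling of samples, with the +1 correction:
    p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).

    When the number of distinct relabelings (the multinomial coefficient
    of the group sizes) does not exceed ``n_permutations``, all of them
    are enumerated and the exact permutation p-value is returned instead.
    """
    groups = np.asarray(groups)
    if len(groups) != dist.n:
        raise ValueError("groups length must match number of samples")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        bad = uniq[counts < 2]
        raise ValueError(f"singleton group(s) not allowed: {list(bad)}")

    n = dist.n
    m = n * (n - 1) // 2
    m_half = m / 2.0
    # rank the condensed dissimilarities, then re-embed as a matrix
    cond = dist.condensed()
    ranks_cond = _sps.rankdata(cond)
    rank_matrix = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    rank_matrix[iu] = ranks_cond
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, groups, m_half)

    n_distinct = _n_distinct_relabelings(counts)
    if n_distinct <= n_permutations:
        perm_rs = _enumerate_relabelings(rank_matrix, groups, m_half)
        # observed labeling is one of the enumerated ones: exact p
        p = float(np.mean(perm_rs >= r_obs - 1e-12))
        return AnosimResult(
            R=r_obs,
            significance=p,
            n_permutations=len(perm_rs),
            seed=seed,
            method="exact",
            permutation_Rs=perm_rs,
        )

    rng = np.random.default_rng(seed)
    perm_rs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        perm_rs[i] = _anosim_r(rank_matrix, groups[perm], m_half)
    count = int(np.sum(perm_rs >= r_obs - 1e-12))
    p = (1.0 + count) / (1.0 + n_permutations)
    return AnosimResult(
        R=r_obs,
        significance=p,
        n_permutations=n_permutations,
        seed=seed,
        method="permutation",
        permutation_Rs=perm_rs,
    )


def _n_distinct_relabelings(counts: np.ndarray) -> float:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _enumerate_relabelings(
    rank_matrix: np.ndarray, groups: np.ndarray, m_half: float
) -> np.ndarray:
    """R statistic under every distinct assignment of labels to samples."""
    n = len(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    rs = []

    def recurse(remaining: frozenset, labels: np.ndarray, gi: int) -> None:
        if gi == len(uniq) - 1:
            lab = labels.copy()
            lab[list(remaining)] = gi
            rs.append(_anosim_r(rank_matrix, lab, m_half))
            return
        for combo in itertools.combinations(sorted(remaining), counts[gi]):
            lab = labels.copy()
            lab[list(combo)] = gi
            recurse(remaining - set(combo), lab, gi + 1)

    recurse(frozenset(range(n)), np.full(n, -1), 0)
    return np.asarray(rs)


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------


def _pav(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares isotonic fit to y."""
    n = len(y)
    out_vals: list[float] = []
    out_wts: list[float] = []
    out_sizes: list[int] = []
    for v in y.astype(float):
        out_vals.append(v)
        out_wts.append(1.0)
        out_sizes.append(1)
        while len(out_vals) > 1 and out_vals[-2] > out_vals[-1]:
            v2, w2, s2 = out_vals.pop(), out_wts.pop(), out_sizes.pop()
            v1, w1, s1 = out_vals.pop(), out_wts.pop(), out_sizes.pop()
            w = w1 + w2
            out_vals.append((v1 * w1 + v2 * w2) / w)
            out_wts.append(w)
            out_sizes.append(s1 + s2)
    result = np.empty(n)
    pos = 0
    for v, s in zip(out_vals, out_sizes):
        result[pos : pos + s] = v
        pos += s
    return result


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical MDS embedding used as the first-restart init."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def _stress1(dist_config: np.ndarray, dhat: np.ndarray) -> float:
    denom = np.sum(dist_config**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist_config - dhat) ** 2) / denom))


def nmds(
    dist: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: Optional[int] = None,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Alternates isotonic (pool-adjacent-violators) regression of the
    configuration distances on the dissimilarity rank order with a Guttman
    majorization update of the configuration. The first restart is
    initialized from classical scaling of the dissimilarities, remaining
    restarts from seeded random configurations; the lowest-stress restart
    is returned. Within a restart the recorded stress sequence is
    non-increasing: an update that would raise stress terminates the
    restart.
    """
    if k < 1 or k >= dist.n:
        raise ValueError("require 1 <= k < n samples")
    d = dist.values
    if not np.all(np.isfinite(d)):
        raise ValueError("dissimilarities must be finite")
    n = dist.n
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    order = np.argsort(delta, kind="stable")

    rng = np.random.default_rng(seed)
    best: Optional[NmdsResult] = None

    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = _classical_scaling(d, k)
        else:
            x = rng.normal(size=(n, k)) * (delta.mean() if delta.mean() > 0 else 1.0)
        history = []
        prev_stress = np.inf
        converged = False
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dmat = np.sqrt((diff**2).sum(axis=2))
            dvec = dmat[iu]
            dhat_sorted = _pav(dvec[order])
            dhat = np.empty_like(dvec)
            dhat[order] = dhat_sorted
            stress = _stress1(dvec, dhat)
            if stress > prev_stress + 1e-15:
                break  # monotone contract: never record an increase
            history.append(stress)
            if prev_stress - stress < tol:
                converged = True
                prev_stress = stress
                break
            prev_stress = stress
            # Guttman transform toward the isotonic targets
            dhat_m = np.zeros((n, n))
            dhat_m[iu] = dhat
            dhat_m = dhat_m + dhat_m.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dmat > 1e-12, dhat_m / np.where(dmat == 0, 1, dmat), 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
            x = x - x.mean(axis=0)
        cand = NmdsResult(
            coordinates=x,
            stress=history[-1] if history else float("inf"),
            n_restarts=n_restarts,
            converged=converged,
            stress_history=history,
        )
        if best is None or cand.stress < best.stress:
            best = cand
        if best.stress <= 1e-12:
            break
    assert best is not None
    best.n_restarts = n_restarts
    return best


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------


def anova_tukey(values: Sequence[float], groups: Sequence, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey's honest-significant-difference post hoc.

    F = MS_between / MS_within on (g-1, N-g) degrees of freedom. Tukey
    adjusted p-values come from the studentized range distribution with
    q = |mean_i - mean_j| / sqrt(MS_within * (1/n_i + 1/n_j) / 2)
    (Tukey-Kramer for unequal group sizes).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    uniq = list(dict.fromkeys(g.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    ys = [y[g == u] for u in uniq]
    ns = np.array([len(v) for v in ys])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 observations")
    big_n = int(ns.sum())
    k = len(uniq)
    grand = y.mean()
    means = np.array([v.mean() for v in ys])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - m) ** 2) for v, m in zip(ys, means)))
    df_b, df_w = k - 1, big_n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w

    degenerate = False
    if ms_within == 0.0:
        if ss_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), np.nextafter(0.0, 1.0)
            degenerate = True
    else:
        f_stat = ms_between / ms_within
        p = float(_sps.f.sf(f_stat, df_b, df_w))
        p = max(p, np.nextafter(0.0, 1.0))

    tukey = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if ms_within == 0.0:
                adj_p = 1.0 if diff == 0 else np.nextafter(0.0, 1.0)
            else:
                se = math.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0)
                q = abs(diff) / se if se > 0 else float("inf")
                adj_p = float(_sps.studentized_range.sf(q, k, df_w))
                adj_p = min(max(adj_p, np.nextafter(0.0, 1.0)), 1.0)
            tukey.append(((uniq[i], uniq[j]), float(diff), adj_p))

    return AnovaResult(
        F=f_stat,
        df_between=df_b,
        df_within=df_w,
        p=float(min(p, 1.0)),
        tukey=tukey,
        degenerate=degenerate,
    )
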