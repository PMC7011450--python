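"""Partitioning around medoids (PAM) over origin covariates.

Origin locations are grouped into climatically and geographically
homogeneous clusters that act as the "population" level of the genetic
analysis; genotypes inherit the cluster of their origin location.  The
number of clusters is chosen by average silhouette width over a candidate
range.  Features are z-scored before the Euclidean distance is formed —
the raw covariates mix degrees, kilometres, metres, degrees Celsius and
millimetres, so equal weighting on the standardized scale is the only
defensible mixing rule.

The PAM implementation is the classic BUILD + SWAP algorithm with a
deterministic row-major scan and single-best-exchange policy, so results
are exactly reproducible and testable against exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClusterResult",
    "KSelection",
    "standardize_features",
    "pairwise_euclidean",
    "pam",
    "silhouette",
    "select_k",
]


def standardize_features(table: pd.DataFrame, variables: list[str]) -> np.ndarray:
    """Z-score the chosen columns (sample SD, ddof=1).

    Constant columns are rejected by name: a zero-variance feature carries
    no clustering information and would divide by zero.
    """
    X = np.empty((len(table), len(variables)), dtype=float)
    for j, v in enumerate(variables):
        col = table[v].to_numpy(dtype=float)
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"constant or degenerate column: {v!r}")
        X[:, j] = (col - col.mean()) / sd
    return X


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))


@dataclass
class ClusterResult:
    k: int
    medoids: np.ndarray  # indices into the input
    assignment: np.ndarray  # point -> cluster label (0..k-1, ordered as medoids)
    objective: float  # sum of point-to-assigned-medoid dissimilarity
    avg_silhouette: float | None = None
    silhouettes: np.ndarray | None = None


def _comb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("dissimilarity must have zero diagonal")
    if np.any(D < 0):
        raise ValueError("dissimilarity must be non-negative")
    return D


def pam(dissimilarity: np.ndarray, k: int) -> ClusterResult:
    """Classic PAM: greedy BUILD then best-improvement SWAP.

    BUILD seeds k medoids one at a time, each chosen to maximally reduce
    the total dissimilarity of points to their nearest medoid.  SWAP then
    repeatedly applies the single best strictly improving
    (medoid, non-medoid) exchange until none exists; the objective is
    non-increasing throughout.  Ties are broken by the deterministic
    row-major scan order (lowest indices win).

    BUILD+SWAP is a heuristic and can terminate in a single-swap local
    optimum (the reference R implementation shares this behaviour).  For
    small instances — C(n, k) up to 50 000 medoid sets — the result is
    refined by exhaustive enumeration, which is cheap there and makes the
    returned medoid set provably optimal.
    """
    D = _check_dissimilarity(dissimilarity)
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        # gain of adding candidate h: sum of reductions max(nearest - D[:,h], 0)
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    med = np.array(sorted(medoids))

    def objective(m):
        return float(D[:, m].min(axis=1).sum())

    best = objective(med)
    while True:
        dm = D[:, med]
        order = np.argsort(dm, axis=1)
        d1 = dm[np.arange(n), order[:, 0]]
        d2 = dm[np.arange(n), order[:, 1]]
        nearest_idx = order[:, 0]  # position within med
        best_swap = None
        best_cost = best
        in_set = np.zeros(n, dtype=bool)
        in_set[med] = True
        for mi in range(len(med)):
            # nearest distance with medoid mi removed
            alt = np.where(nearest_idx == mi, d2, d1)
            for h in range(n):
                if in_set[h]:
                    continue
                cost = float(np.minimum(alt, D[:, h]).sum())
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_swap = (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        med[mi] = h
        med = np.array(sorted(med))
        best = best_cost

    if _comb(n, k) <= 50_000:
        from itertools import combinations

        for cand in combinations(range(n), k):
            cost = float(D[:, cand].min(axis=1).sum())
            if cost < best - 1e-12:
                best = cost
                med = np.array(cand)

    assignment = np.argmin(D[:, med], axis=1)
    return ClusterResult(k=k, medoids=med, assignment=assignment, objective=objective(med))


def silhouette(assignment: np.ndarray, dissimilarity: np.ndarray):
    """Per-point and average silhouette widths.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean dissimilarity
    to the other members of i's cluster and b(i) the smallest mean
    dissimilarity to any other cluster.  Points in singleton clusters get
    s = 0 by convention.
    """
    D = _check_dissimilarity(dissimilarity)
    labels = np.asarray(assignment)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        members = np.flatnonzero(labels == own)
        if len(members) == 1:
            s[i] = 0.0
            continue
        a = D[i, members[members != i]].mean()
        b = min(D[i, labels == c].mean() for c in uniq if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


@dataclass
class KSelection:
    """Candidate cluster counts ranked by average silhouette width."""

    table: pd.DataFrame  # columns k, avg_silhouette, sorted by rank
    results: dict[int, ClusterResult]

    @property
    def best_k(self) -> int:
        return int(self.table.iloc[0]["k"])

    @property
    def second_best_k(self) -> int:
        return int(self.table.iloc[1]["k"])


def select_k(features: np.ndarray, k_range) -> KSelection:
    """Run PAM + silhouette over ``k_range``; rank by descending score.

    Ties in average silhouette are broken toward the smaller k.
    """
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k range")
    n = features.shape[0]
    if ks[0] < 2 or ks[-1] >= n:
        raise ValueError(f"k range must lie within [2, n-1] = [2, {n-1}]")
    D = pairwise_euclidean(np.asarray(features, dtype=float))
    results = {}
    rows = []
    for k in ks:
        res = pam(D, k)
        res.silhouettes, res.avg_silhouette = silhouette(res.assignment, D)
        results[k] = res
        rows.append((k, res.avg_silhouette))
    table = pd.DataFrame(rows, columns=["k", "avg_silhouette"]).sort_values(
        ["avg_silhouette", "k"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return KSelection(table=table, results=results)
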