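"""Partitioning Around Medoids on a precomputed distance matrix.

Initialisation is either BUILD (greedy, deterministic, the default) or a
seeded random draw of K medoids.  The refinement phase is a steepest-descent
swap search: every (medoid, non-medoid) exchange is scored and the single
best strictly cost-decreasing swap is applied per iteration until none
exists, so the total cost (sum of distances from each sample to its nearest
medoid) is non-increasing and the result is a local optimum.  All ties break
toward the lowest index for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio.stats.distance import DistanceMatrix


@dataclass
class ClusteringResult:
    K: int
    medoid_indices: np.ndarray
    assignment: np.ndarray  # per-sample cluster id in 1..K
    total_cost: float
    n_iterations: int
    seed: int | None = None
    sample_ids: list[str] | None = None


def _as_matrix(dm) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(dm, DistanceMatrix):
        return np.asarray(dm.data, dtype=float), list(dm.ids)
    return np.asarray(dm, dtype=float), None


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]  # (n, K)
    nearest = np.argmin(sub, axis=1)  # ties -> lower index
    cost = float(sub[np.arange(D.shape[0]), nearest].sum())
    return nearest, cost


def _build_init(D: np.ndarray, K: int) -> np.ndarray:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nd = D[:, medoids[0]].copy()
    for _ in range(1, K):
        gains = np.maximum(nd[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nd = np.minimum(nd, D[:, c])
    return np.asarray(sorted(medoids))


def pam(
    dm,
    K: int,
    init: str = "build",
    seed: int | None = None,
    max_iter: int = 200,
) -> ClusteringResult:
    """Run PAM for a fixed number of clusters K on a distance matrix."""
    D, ids = _as_matrix(dm)
    n = D.shape[0]
    if not 2 <= K < n:
        raise ValueError(f"K={K} must satisfy 2 <= K < n={n}")
    if init == "build":
        medoids = _build_init(D, K)
    elif init == "random":
        rng = np.random.default_rng(seed)
        medoids = np.sort(rng.choice(n, size=K, replace=False))
    else:
        raise ValueError(f"unknown init {init!r}")

    prev_cost = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sub = D[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        nearest = order[:, 0]
        nd = sub[np.arange(n), nearest]
        cost = float(nd.sum())
        assert cost <= prev_cost + 1e-9, "swap phase increased total cost"
        prev_cost = cost
        second = sub[np.arange(n), order[:, 1]] if K > 1 else np.full(n, np.inf)

        non_medoids = np.setdiff1d(np.arange(n), medoids)
        Dj = D[:, non_medoids]  # (n, n-K)
        keep = np.minimum(nd[:, None], Dj)  # point keeps its medoid set minus none
        lose = np.minimum(second[:, None], Dj)  # point's medoid was removed
        base = keep.sum(axis=0)  # (n-K,) cost if j added and no removal mattered
        diff = lose - keep
        onehot = np.zeros((K, n))
        onehot[nearest, np.arange(n)] = 1.0
        newcost = base[None, :] + onehot @ diff  # (K, n-K)

        best_flat = int(np.argmin(newcost))
        bm, bj = divmod(best_flat, newcost.shape[1])
        if newcost[bm, bj] < cost - 1e-12:
            med = medoids.copy()
            med[bm] = non_medoids[bj]
            medoids = np.sort(med)
        else:
            break

    nearest, cost = _assign(D, medoids)
    return ClusteringResult(
        K=K,
        medoid_indices=medoids,
        assignment=nearest + 1,
        total_cost=cost,
        n_iterations=n_iter,
        seed=seed,
        sample_ids=ids,
    )


def pam_sweep(
    dm,
    k_range=(2, 10),
    init: str = "build",
    seed: int | None = None,
) -> list[ClusteringResult]:
    """One PAM run per K across an inclusive range (capped at n-1)."""
    D, _ = _as_matrix(dm)
    lo, hi = int(k_range[0]), int(k_range[1])
    hi = min(hi, D.shape[0] - 1)
    if lo < 2 or lo > hi:
        raise ValueError(f"invalid K range [{lo}, {hi}] for n={D.shape[0]}")
    return [pam(dm, K, init=init, seed=seed) for K in range(lo, hi + 1)]
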