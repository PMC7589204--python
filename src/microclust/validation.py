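"""Internal cluster-validity indices and external agreement measures.

Internal indices score a partition from the distance matrix alone and drive
the choice of K: Dunn (max), Silhouette (max), Xie-Beni (min) and
Wemmert-Gancarski (max); the last two use medoids as cluster centres.
External measures compare a partition against known labels: matched accuracy
(best injective mapping between predicted clusters and true classes, found by
the Hungarian algorithm on the contingency table) and the matched-set Jaccard
index (mean |C∩K|/|C∪K| over the matched pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio.stats.distance import DistanceMatrix

from .pam import ClusteringResult

INDEX_DIRECTIONS = {
    "dunn": "max",
    "silhouette": "max",
    "xie_beni": "min",
    "wemmert_gancarski": "max",
}


@dataclass
class ExternalScores:
    accuracy: float
    jaccard: float
    matching: list[tuple[int, int]]  # (predicted cluster, true class) pairs


def _as_matrix(dm) -> np.ndarray:
    if isinstance(dm, DistanceMatrix):
        return np.asarray(dm.data, dtype=float)
    return np.asarray(dm, dtype=float)


def _groups(assignment) -> list[np.ndarray]:
    a = np.asarray(assignment)
    return [np.flatnonzero(a == lbl) for lbl in np.unique(a)]


def dunn_index(dm, assignment) -> float:
    """Min single-linkage inter-cluster distance / max cluster diameter."""
    D = _as_matrix(dm)
    groups = _groups(assignment)
    if len(groups) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    diam = max(
        (D[np.ix_(g, g)].max() for g in groups if g.size > 1),
        default=0.0,
    )
    if diam == 0.0:
        raise ValueError("Dunn index undefined: all cluster diameters are zero")
    sep = min(
        D[np.ix_(g1, g2)].min()
        for i, g1 in enumerate(groups)
        for g2 in groups[i + 1 :]
    )
    return float(sep / diam)


def silhouette_index(dm, assignment) -> float:
    """Mean silhouette width; singleton clusters contribute 0 (a = 0 convention)."""
    D = _as_matrix(dm)
    a = np.asarray(assignment)
    groups = _groups(a)
    if len(groups) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = D.shape[0]
    scores = np.zeros(n)
    for gi, g in enumerate(groups):
        for i in g:
            if g.size == 1:
                scores[i] = 0.0
                continue
            a_i = D[i, g].sum() / (g.size - 1)
            b_i = min(D[i, h].mean() for hj, h in enumerate(groups) if hj != gi)
            scores[i] = 0.0 if max(a_i, b_i) == 0 else (b_i - a_i) / max(a_i, b_i)
    return float(scores.mean())


def xie_beni_index(dm, result: ClusteringResult) -> float:
    """Sum of squared point-to-medoid distances over n times the squared
    minimum medoid separation (smaller is better)."""
    D = _as_matrix(dm)
    med = np.asarray(result.medoid_indices)
    a = np.asarray(result.assignment)
    n = D.shape[0]
    labels = np.unique(a)
    within = 0.0
    for lbl, m in zip(labels, med):
        pts = np.flatnonzero(a == lbl)
        within += float((D[pts, m] ** 2).sum())
    seps = [
        D[m1, m2] for i, m1 in enumerate(med) for m2 in med[i + 1 :]
    ]
    min_sep = min(seps)
    if min_sep == 0:
        raise ValueError("Xie-Beni undefined: coincident medoids")
    return within / (n * min_sep**2)


def wemmert_gancarski_index(dm, result: ClusteringResult) -> float:
    """Mean over clusters (weighted by size) of max(0, 1 - mean ratio of the
    distance to the own medoid over the distance to the nearest foreign
    medoid); larger is better."""
    D = _as_matrix(dm)
    med = np.asarray(result.medoid_indices)
    a = np.asarray(result.assignment)
    n = D.shape[0]
    labels = np.unique(a)
    total = 0.0
    for ki, (lbl, m) in enumerate(zip(labels, med)):
        pts = np.flatnonzero(a == lbl)
        others = np.delete(med, ki)
        own = D[pts, m]
        foreign = D[np.ix_(pts, others)].min(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(foreign > 0, own / np.where(foreign > 0, foreign, 1.0), np.inf)
        total += pts.size * max(0.0, 1.0 - float(ratio.mean()))
    return total / n


def score_index(dm, result: ClusteringResult, index_name: str) -> float:
    if index_name == "dunn":
        return dunn_index(dm, result.assignment)
    if index_name == "silhouette":
        return silhouette_index(dm, result.assignment)
    if index_name == "xie_beni":
        return xie_beni_index(dm, result)
    if index_name == "wemmert_gancarski":
        return wemmert_gancarski_index(dm, result)
    raise ValueError(f"unknown index {index_name!r}")


def select_k(dm, results: list[ClusteringResult], index_name: str = "dunn") -> ClusteringResult:
    """Pick the sweep result extremising the index (ties -> smaller K)."""
    if not results:
        raise ValueError("no clustering results")
    direction = INDEX_DIRECTIONS[index_name]
    scores = [score_index(dm, r, index_name) for r in results]
    best, best_score = None, None
    for r, s in sorted(zip(results, scores), key=lambda rs: rs[0].K):
        better = (
            best is None
            or (direction == "max" and s > best_score + 1e-12)
            or (direction == "min" and s < best_score - 1e-12)
        )
        if better:
            best, best_score = r, s
    return best


def _contingency(predicted, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.size != t.size:
        raise ValueError("predicted and true labels differ in length")
    plabels, pinv = np.unique(p, return_inverse=True)
    tlabels, tinv = np.unique(t, return_inverse=True)
    table = np.zeros((plabels.size, tlabels.size), dtype=np.int64)
    np.add.at(table, (pinv, tinv), 1)
    return table, plabels, tlabels


def matched_accuracy(predicted, truth, max_groups: int | None = None) -> ExternalScores:
    """Best-mapping external accuracy and matched-set Jaccard.

    The optimal injective mapping between predicted clusters and true classes
    maximises the number of agreeing samples; samples in unmatched predicted
    clusters count as incorrect.
    """
    table, plabels, tlabels = _contingency(predicted, truth)
    c, k = table.shape
    if max_groups is not None and max(c, k) > max_groups:
        raise ValueError(f"group count exceeds cap {max_groups}")
    rows, cols = linear_sum_assignment(table, maximize=True)
    n = table.sum()
    accuracy = float(table[rows, cols].sum() / n)
    matching = [(int(plabels[r]), int(tlabels[col])) for r, col in zip(rows, cols)]
    psizes = table.sum(axis=1)
    tsizes = table.sum(axis=0)
    jac = [
        table[r, col] / (psizes[r] + tsizes[col] - table[r, col])
        for r, col in zip(rows, cols)
    ]
    return ExternalScores(accuracy=accuracy, jaccard=float(np.mean(jac)), matching=matching)


def jaccard_score(predicted, truth, matching=None) -> float:
    """Matched-set Jaccard: mean |C∩K|/|C∪K| over matched (cluster, class)
    pairs; under balanced two-class symmetric errors this equals a/(2-a) for
    accuracy a."""
    if matching is None:
        return matched_accuracy(predicted, truth).jaccard
    p = np.asarray(predicted)
    t = np.asarray(truth)
    vals = []
    for c_lbl, k_lbl in matching:
        C = p == c_lbl
        K = t == k_lbl
        union = (C | K).sum()
        vals.append(0.0 if union == 0 else (C & K).sum() / union)
    return float(np.mean(vals))
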