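"""Beta-diversity distance matrices.

Mixture-based distances: for one OTU, every subject owns a posterior category
distribution P_i over (z, 0, 1, ..., C, >C).  The discrete L2 PDF distance is
||P_i - P_j||_2, the discrete L2 CDF distance the same norm on the running
sums, and the continuous L2 CDF distance integrates the squared difference of
the step CDFs over [0, C].  Because P_i = w_i' P under a shared component
category matrix P, each of these is equally a quadratic form in the posterior
weight difference (w_i - w_j); both routes are implemented and must agree.

Baselines on relative abundances: Manhattan, Euclidean, Bray-Curtis (with the
epsilon-guarded denominator), weighted and generalized UniFrac, and an
optional log transform applied upstream of the first three.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .io import RelativeAbundanceTable
from .mixture import ComponentGrid

EPSILON = 1e-8


def _as_dm(values: np.ndarray, ids) -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids=list(map(str, ids)))


def _stack_categories(mixtures, attr: str) -> np.ndarray:
    lengths = {len(getattr(m, attr)) for m in mixtures}
    if len(lengths) != 1:
        raise ValueError("subject mixtures do not share one component grid")
    return np.vstack([getattr(m, attr) for m in mixtures])


def l2_discrete_pdf(mixtures, sample_ids=None) -> DistanceMatrix:
    """Pairwise sqrt(sum_q (P_i(q) - P_j(q))^2) over the category grid."""
    P = _stack_categories(mixtures, "category_pdf")
    ids = sample_ids if sample_ids is not None else [
        m.subject if m.subject is not None else str(i) for i, m in enumerate(mixtures)
    ]
    return _as_dm(squareform(pdist(P, metric="euclidean")), ids)


def l2_discrete_cdf(mixtures, sample_ids=None) -> DistanceMatrix:
    """As :func:`l2_discrete_pdf` with the category CDFs F_i in place of P_i."""
    F = _stack_categories(mixtures, "category_cdf")
    ids = sample_ids if sample_ids is not None else [
        m.subject if m.subject is not None else str(i) for i, m in enumerate(mixtures)
    ]
    return _as_dm(squareform(pdist(F, metric="euclidean")), ids)


def cdf_step_matrix(grid: ComponentGrid, cat_matrix: np.ndarray) -> np.ndarray:
    """S[m, j] = F_m(j), the continuous-time step CDF of component m on [j, j+1).

    The zero point mass has F = 1 on all of [0, C] (its mass sits below any
    positive count), the high point mass F = 0, and a gamma component the
    running sum of its count probabilities.
    """
    C = grid.cutoff
    # cat_matrix columns: (z, 0..C, h).  F_m(j) = P(z) + P(0..j).
    cum = np.cumsum(cat_matrix[:, : C + 1 + 1], axis=1)  # includes z and 0..C
    return cum[:, 1 : C + 1]  # F at j = 0..C-1 (value on [j, j+1))


def cdf_gram_matrix(grid: ComponentGrid, cat_matrix: np.ndarray) -> np.ndarray:
    """G[q1, q2] = integral_0^C F_q1(k) F_q2(k) dk, exact for step CDFs."""
    S = cdf_step_matrix(grid, cat_matrix)
    return S @ S.T


def l2_continuous_cdf(
    mixtures=None,
    gram: np.ndarray | None = None,
    grid: ComponentGrid | None = None,
    cat_matrix: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    sample_ids=None,
) -> DistanceMatrix:
    """Continuous L2 CDF distance sqrt((w_i-w_j)' G (w_i-w_j)).

    Either ``mixtures`` (carrying posterior weights) or an explicit ``weights``
    matrix may be given; ``gram`` defaults to the exact step-CDF Gram matrix
    built from ``grid`` and ``cat_matrix``.
    """
    if weights is None:
        weights = np.vstack([m.weights for m in mixtures])
    if gram is None:
        if grid is None or cat_matrix is None:
            raise ValueError("need either a Gram matrix or (grid, cat_matrix)")
        gram = cdf_gram_matrix(grid, cat_matrix)
    # G = S S', so the quadratic form is the squared Euclidean norm of S'(w_i-w_j)
    vals, vecs = np.linalg.eigh(gram)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise ValueError("Gram matrix is not positive semidefinite")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    feats = weights @ root
    D = squareform(pdist(feats, metric="euclidean"))
    ids = sample_ids if sample_ids is not None else (
        [m.subject if m.subject is not None else str(i) for i, m in enumerate(mixtures)]
        if mixtures is not None
        else [str(i) for i in range(weights.shape[0])]
    )
    return _as_dm(D, ids)


def combine_across_otus(per_otu: list[DistanceMatrix], rule: str = "l2") -> DistanceMatrix:
    """Aggregate per-OTU distance matrices across OTUs.

    ``l2`` (default) takes the root-sum-of-squares (the concatenated-coordinate
    reading), ``sum`` and ``mean`` the plain sum / average.
    """
    if not per_otu:
        raise ValueError("no distance matrices to combine")
    ids = list(per_otu[0].ids)
    for dm in per_otu[1:]:
        if list(dm.ids) != ids:
            raise ValueError("mismatched sample sets across OTUs")
    stack = np.stack([dm.data for dm in per_otu])
    if rule == "l2":
        out = np.sqrt((stack**2).sum(axis=0))
    elif rule == "sum":
        out = stack.sum(axis=0)
    elif rule == "mean":
        out = stack.mean(axis=0)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return _as_dm(out, ids)


def _values_and_ids(table):
    if isinstance(table, RelativeAbundanceTable):
        return table.values, table.sample_ids
    return np.asarray(table, dtype=float), [str(i) for i in range(len(table))]


def manhattan(table) -> DistanceMatrix:
    X, ids = _values_and_ids(table)
    return _as_dm(squareform(pdist(X, metric="cityblock")), ids)


def euclidean(table) -> DistanceMatrix:
    X, ids = _values_and_ids(table)
    return _as_dm(squareform(pdist(X, metric="euclidean")), ids)


def bray_curtis(table, epsilon: float = EPSILON) -> DistanceMatrix:
    """sum|x_j - x_k| / (sum(x_j + x_k) + epsilon); the epsilon guard keeps
    all-zero sample pairs at distance 0 rather than NaN."""
    X, ids = _values_and_ids(table)
    num = squareform(pdist(X, metric="cityblock"))
    tot = X.sum(axis=1)
    den = tot[:, None] + tot[None, :] + epsilon
    return _as_dm(num / den, ids)


def _branch_table(tree: TreeNode, otu_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths b and the branch x OTU descendant-incidence matrix."""
    col = {o: j for j, o in enumerate(otu_ids)}
    missing = [t.name for t in tree.tips() if t.name not in col]
    leaves_seen = {t.name for t in tree.tips()}
    absent = [o for o in otu_ids if o not in leaves_seen]
    if absent:
        raise ValueError(f"missing leaves for OTUs: {absent}")
    lengths, rows = [], []
    for node in tree.postorder(include_self=False):
        b = node.length if node.length is not None else 0.0
        if b < 0:
            raise ValueError("negative branch length")
        row = np.zeros(len(otu_ids))
        for tip in node.tips(include_self=True):
            if tip.name in col:
                row[col[tip.name]] = 1.0
        lengths.append(b)
        rows.append(row)
    return np.asarray(lengths), np.vstack(rows)


def weighted_unifrac(table, tree: TreeNode, epsilon: float = EPSILON) -> DistanceMatrix:
    """sum_i b_i |x_ij - x_ik| / (sum_i b_i (x_ij + x_ik) + epsilon), where
    x_ij is the abundance of sample j descending through branch i."""
    X, ids = _values_and_ids(table)
    otu_ids = table.otu_ids if isinstance(table, RelativeAbundanceTable) else [
        str(i) for i in range(X.shape[1])
    ]
    b, inc = _branch_table(tree, list(otu_ids))
    A = X @ inc.T  # (samples, branches)
    num = squareform(pdist(A, metric="cityblock", w=b))
    wtot = A @ b
    den = wtot[:, None] + wtot[None, :] + epsilon
    return _as_dm(num / den, ids)


def generalized_unifrac(
    table, tree: TreeNode, alpha: float = 0.5, epsilon: float = EPSILON
) -> DistanceMatrix:
    """Generalized UniFrac with abundance exponent alpha (0.5 by default);
    branch terms with zero combined abundance contribute zero."""
    X, ids = _values_and_ids(table)
    otu_ids = table.otu_ids if isinstance(table, RelativeAbundanceTable) else [
        str(i) for i in range(X.shape[1])
    ]
    b, inc = _branch_table(tree, list(otu_ids))
    A = X @ inc.T
    n = A.shape[0]
    out = np.zeros((n, n))
    for j in range(n):
        s = A[j][None, :] + A[j + 1 :]  # (n-j-1, branches)
        d = np.abs(A[j][None, :] - A[j + 1 :])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(s > 0, d / np.where(s > 0, s, 1.0), 0.0)
            spow = np.where(s > 0, s**alpha, 0.0)
        num = (b[None, :] * spow * ratio).sum(axis=1)
        den = (b[None, :] * spow).sum(axis=1) + epsilon
        out[j, j + 1 :] = num / den
    out = out + out.T
    return _as_dm(out, ids)


def log_transform(table, pseudo: float = EPSILON):
    """Entrywise log(x + pseudo); feeds unchanged into the simple distances."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    if isinstance(table, RelativeAbundanceTable):
        return RelativeAbundanceTable(
            list(table.sample_ids),
            list(table.otu_ids),
            np.log(table.values + pseudo),
            list(table.zero_total_samples),
        )
    return np.log(np.asarray(table, dtype=float) + pseudo)
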