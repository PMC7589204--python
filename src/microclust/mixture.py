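"""Per-OTU zero-inflated count mixture model.

One OTU at a time, the observed counts across I subjects are modelled as a
mixture over a fixed grid of components:

* a zero point mass (structural zeros: the subject never carries the taxon),
* a small set of left-skewed low-rate Gamma components for rates near zero,
* Gamma(n+1, 1) components — the posterior of a Poisson rate given count n —
  covering the bulk of the count range,
* sparser high-range Gamma components placed on a log-uniform knot grid,
* a high point mass absorbing counts above a cutoff C.

Conditional on a subject's relative sequencing resolution t_i, a Gamma(a, b)
rate component yields negative-binomial counts NB(a, b/(t_i+b)).  Population
mixture weights are estimated by least squares on the aggregated count
spectrum y_k (number of subjects observing exactly k) under a simplex
constraint, with bootstrap replicates used both to select among candidate
component grids and to average the weight estimates.  Subject-specific
mixtures are the Bayes posteriors over components given (n_i, t_i), and their
category distributions over (z, 0, 1, ..., C, >C) are the objects the L2
beta-diversity distances operate on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.special import gammaln

ZERO = "zero_mass"
GAMMA = "gamma"
HIGH = "high_mass"

_T_FLOOR = 1e-6


@dataclass(frozen=True)
class Component:
    kind: str
    shape: float = float("nan")
    rate: float = float("nan")

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class ComponentGrid:
    """Ordered component list (zero mass, gammas by increasing mean, high mass)."""

    components: tuple[Component, ...]
    cutoff: int

    def __post_init__(self) -> None:
        kinds = [c.kind for c in self.components]
        if kinds[0] != ZERO or kinds[-1] != HIGH or kinds.count(ZERO) != 1 or kinds.count(HIGH) != 1:
            raise ValueError("grid must be (zero_mass, gammas..., high_mass)")
        means = [c.mean for c in self.components if c.kind == GAMMA]
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            raise ValueError("gamma components must be ordered by increasing mean")
        if self.cutoff < 1:
            raise ValueError("cutoff must be a positive integer")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_categories(self) -> int:
        """Categories (z, 0, 1, ..., C, h)."""
        return self.cutoff + 3

    def gamma_components(self) -> list[Component]:
        return [c for c in self.components if c.kind == GAMMA]


@dataclass
class PopulationMixture:
    """Estimated population-level mixture for one OTU."""

    grid: ComponentGrid
    weights: np.ndarray
    objective: float
    n_bootstrap: int = 0
    seed: int | None = None
    selection: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable record of the fitted mixture."""
        return {
            "cutoff": self.grid.cutoff,
            "components": [
                {"kind": c.kind}
                if c.kind != GAMMA
                else {"kind": c.kind, "shape": c.shape, "rate": c.rate}
                for c in self.grid.components
            ],
            "weights": np.asarray(self.weights).tolist(),
            "objective": self.objective,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


@dataclass
class SubjectMixture:
    """Posterior mixture for one subject given (n_i, t_i)."""

    subject: object
    weights: np.ndarray
    category_pdf: np.ndarray
    category_cdf: np.ndarray


def compute_relative_resolution(
    sample_totals, zero_total: str = "error", floor: float = _T_FLOOR
) -> np.ndarray:
    """t_i = N_i / mean(N), the per-sample depth relative to the average depth.

    ``zero_total`` controls samples with no reads: ``"error"`` (default)
    raises, ``"floor"`` replaces t_i = 0 with a tiny positive value (under
    which every component predicts count 0 — the correct degenerate limit).
    """
    totals = np.asarray(sample_totals, dtype=float)
    if totals.ndim == 2:  # accept a count table matrix directly
        totals = totals.sum(axis=1)
    if totals.sum() == 0:
        raise ValueError("all sample totals are zero")
    t = totals / totals.mean()
    if (t == 0).any():
        if zero_total == "error":
            raise ValueError(
                f"{int((t == 0).sum())} sample(s) have zero total reads; "
                "pass zero_total='floor' to epsilon-guard them"
            )
        t = np.maximum(t, floor)
    return t


def build_component_grid(
    counts_for_otu,
    cutoff: int | None = None,
    cutoff_quantile: float = 0.99,
    c_mid: int | None = None,
    n_high_knots: int = 5,
    low_rate_shape: float = 0.5,
    low_rate_means: tuple[float, ...] = (0.1, 0.3, 0.6),
) -> ComponentGrid:
    """Build the fixed component grid for one OTU's counts.

    The cutoff C defaults to the counts' ``cutoff_quantile`` quantile (rounded
    up, at least 10); C_mid to min(10, C-1).  High-range knots are the rounded
    exponentials of an even grid on [log C_mid, log C], each contributing a
    Gamma(knot+1, 1) component.
    """
    counts = np.asarray(counts_for_otu)
    if counts.size == 0 or (counts <= 0).all():
        raise ValueError("grid undefined: no positive counts")
    if cutoff is None:
        cutoff = max(10, int(math.ceil(np.quantile(counts, cutoff_quantile))))
    if c_mid is None:
        c_mid = min(10, cutoff - 1)
    if c_mid >= cutoff:
        raise ValueError(f"C_mid={c_mid} must be < C={cutoff}")
    if c_mid < 1:
        raise ValueError("C_mid must be >= 1")

    comps: list[Component] = [Component(ZERO)]
    for m in low_rate_means:
        comps.append(Component(GAMMA, shape=low_rate_shape, rate=low_rate_shape / m))
    for n in range(0, c_mid + 1):
        comps.append(Component(GAMMA, shape=float(n + 1), rate=1.0))
    knots = np.exp(np.linspace(math.log(c_mid), math.log(cutoff), n_high_knots))
    for k in np.round(knots).astype(int):
        comps.append(Component(GAMMA, shape=float(k + 1), rate=1.0))
    # dedupe identical (shape, rate) pairs, keep gamma components ordered by mean
    gammas = sorted(
        {(c.shape, c.rate) for c in comps if c.kind == GAMMA}, key=lambda p: p[0] / p[1]
    )
    ordered = (
        [Component(ZERO)]
        + [Component(GAMMA, shape=s, rate=r) for s, r in gammas]
        + [Component(HIGH)]
    )
    return ComponentGrid(tuple(ordered), cutoff=int(cutoff))


def component_count_pmf(component: Component, k, t) -> np.ndarray:
    """P(K = k | component, resolution t), vectorised over k.

    Gamma(a, b) thinned by Poisson(lambda * t) gives the negative binomial
    C(k+a-1, k) (b/(t+b))^a (t/(t+b))^k.  The zero point mass puts all mass on
    k = 0 and the high point mass none on any finite k <= C (its mass lives in
    the tail category).
    """
    k = np.asarray(k)
    if component.kind == ZERO:
        return (k == 0).astype(float)
    if component.kind == HIGH:
        return np.zeros(k.shape, dtype=float)
    a, b = component.shape, component.rate
    t = float(t)
    if t <= 0:
        return (k == 0).astype(float)
    logp = (
        gammaln(k + a)
        - gammaln(a)
        - gammaln(k + 1)
        + a * (math.log(b) - math.log(t + b))
        + k * (math.log(t) - math.log(t + b))
    )
    return np.exp(logp)


def _gamma_pmf_matrix(shape: float, rate: float, kmax: int, t: np.ndarray) -> np.ndarray:
    """(kmax+1, I) negative-binomial pmf table for one gamma component."""
    k = np.arange(kmax + 1, dtype=float)[:, None]
    t = np.asarray(t, dtype=float)[None, :]
    tt = np.maximum(t, _T_FLOOR)
    logp = (
        gammaln(k + shape)
        - gammaln(shape)
        - gammaln(k + 1)
        + shape * (np.log(rate) - np.log(tt + rate))
        + k * (np.log(tt) - np.log(tt + rate))
    )
    return np.exp(logp)


def component_pmf_tensor(grid: ComponentGrid, t) -> np.ndarray:
    """Per-subject count pmf tensor P[m, k, i] for k = 0..C.

    The implied tail mass P(K > C) of component m for subject i is
    ``1 - P[m].sum(axis=0)`` (exactly 1 for the high point mass, 0 for the
    zero point mass).
    """
    t = np.asarray(t, dtype=float)
    C = grid.cutoff
    M, I = grid.n_components, t.size
    out = np.zeros((M, C + 1, I))
    cache: dict[tuple[float, float], np.ndarray] = {}
    for m, comp in enumerate(grid.components):
        if comp.kind == ZERO:
            out[m, 0, :] = 1.0
        elif comp.kind == HIGH:
            pass
        else:
            key = (comp.shape, comp.rate)
            if key not in cache:
                cache[key] = _gamma_pmf_matrix(comp.shape, comp.rate, C, t)
            out[m] = cache[key]
    return out


def aggregate_counts(counts_for_otu, cutoff: int) -> np.ndarray:
    """Aggregated count spectrum y: y[k] = #subjects with count k (k=0..C) plus
    a final tail bin for counts > C."""
    counts = np.asarray(counts_for_otu)
    clipped = np.minimum(counts, cutoff + 1)
    return np.bincount(clipped, minlength=cutoff + 2).astype(float)


def _design_matrix(pmf_tensor: np.ndarray) -> np.ndarray:
    """(C+2, M) subject-averaged bin probabilities p_km, tail bin last."""
    pbar = pmf_tensor.mean(axis=2)  # (M, C+1)
    tail = np.clip(1.0 - pbar.sum(axis=1), 0.0, 1.0)  # (M,)
    return np.vstack([pbar.T, tail[None, :]])


def expected_aggregated_counts(
    grid: ComponentGrid, weights, t, pmf_tensor: np.ndarray | None = None
) -> np.ndarray:
    """Expected spectrum yhat_k = sum_m w_m p_km I (tail bin included)."""
    weights = np.asarray(weights, dtype=float)
    if pmf_tensor is None:
        pmf_tensor = component_pmf_tensor(grid, t)
    I = pmf_tensor.shape[2]
    P = _design_matrix(pmf_tensor)
    return I * (P @ weights)


def simplex_lstsq(A: np.ndarray, b: np.ndarray, tol: float = 1e-11) -> tuple[np.ndarray, float]:
    """Exact active-set solver for min ||A w - b||^2 s.t. sum(w)=1, w >= 0.

    Lawson-Hanson-style: repeatedly solve the equality-constrained problem on
    the free set via its KKT system, step the feasible iterate to the boundary
    when a free variable would go negative, and release the active variable
    with the most negative multiplier until the KKT conditions hold.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    Q = A.T @ A
    c = A.T @ b
    ridge = 1e-12 * max(np.trace(Q) / n, 1.0)

    def eq_solve(free_idx: np.ndarray) -> np.ndarray:
        f = free_idx.size
        if f == 1:
            return np.array([1.0])
        K = np.zeros((f + 1, f + 1))
        K[:f, :f] = 2.0 * (Q[np.ix_(free_idx, free_idx)] + ridge * np.eye(f))
        K[:f, f] = 1.0
        K[f, :f] = 1.0
        rhs = np.concatenate([2.0 * c[free_idx], [1.0]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        return sol[:f]

    w = np.full(n, 1.0 / n)
    free = np.ones(n, dtype=bool)
    gscale = max(np.abs(c).max(), 1.0)
    for _ in range(50 * n):
        idx = np.flatnonzero(free)
        z = np.zeros(n)
        z[idx] = eq_solve(idx)
        if (z[idx] >= -tol).all():
            w = np.clip(z, 0.0, None)
            w /= w.sum()
            g = 2.0 * (Q @ w - c)
            lam = g[idx].mean()
            mu = g - lam
            bound = np.flatnonzero(~free)
            if bound.size == 0 or (mu[bound] >= -1e-7 * gscale).all():
                break
            free[bound[np.argmin(mu[bound])]] = True
        else:
            d = z - w
            neg = free & (z < -tol)
            steps = w[neg] / (w[neg] - z[neg])
            alpha = float(np.min(steps))
            w = w + alpha * d
            w = np.clip(w, 0.0, None)
            hit = neg & (w <= tol)
            free[hit] = False
            w[~free] = 0.0
            s = w.sum()
            if s > 0:
                w /= s
    resid = A @ w - b
    return w, float(resid @ resid)


def simplex_lstsq_penalized(A: np.ndarray, b: np.ndarray, rho: float | None = None) -> tuple[np.ndarray, float]:
    """Fallback: NNLS with an appended sum-to-one row, renormalised."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if rho is None:
        rho = 1e3 * max(np.abs(b).max(), 1.0)
    Aa = np.vstack([A, rho * np.ones((1, A.shape[1]))])
    ba = np.concatenate([b, [rho]])
    w, _ = nnls(Aa, ba)
    s = w.sum()
    if s == 0:
        w = np.full(A.shape[1], 1.0 / A.shape[1])
    else:
        w = w / s
    resid = A @ w - b
    return w, float(resid @ resid)


def estimate_weights(
    grid: ComponentGrid,
    observed: np.ndarray,
    t,
    pmf_tensor: np.ndarray | None = None,
    method: str = "active-set",
) -> PopulationMixture:
    """Simplex-constrained least-squares fit of mixture weights to the
    observed aggregated count spectrum."""
    y = np.asarray(observed, dtype=float)
    if pmf_tensor is None:
        pmf_tensor = component_pmf_tensor(grid, t)
    I = pmf_tensor.shape[2]
    if y.size != grid.cutoff + 2:
        raise ValueError("observed spectrum inconsistent with grid cutoff")
    A = I * _design_matrix(pmf_tensor)
    if method == "active-set":
        w, obj = simplex_lstsq(A, y)
    elif method == "penalized-nnls":
        w, obj = simplex_lstsq_penalized(A, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    uniform = np.full(grid.n_components, 1.0 / grid.n_components)
    r0 = A @ uniform - y
    assert obj <= float(r0 @ r0) + 1e-6, "solver worse than uniform start"
    return PopulationMixture(grid=grid, weights=w, objective=obj)


def default_candidate_grids(
    counts_for_otu,
    cutoff: int | None = None,
    cutoff_quantile: float = 0.99,
    c_mid_values: tuple[int, ...] = (5, 10),
    knot_values: tuple[int, ...] = (3, 5),
) -> list[ComponentGrid]:
    """Candidate model family: the C_mid x high-knot grid, shared cutoff."""
    counts = np.asarray(counts_for_otu)
    if cutoff is None:
        cutoff = max(10, int(math.ceil(np.quantile(counts, cutoff_quantile))))
    grids, seen = [], set()
    for cm in c_mid_values:
        cm = min(cm, cutoff - 1)
        if cm < 1:
            continue
        for nk in knot_values:
            g = build_component_grid(counts, cutoff=cutoff, c_mid=cm, n_high_knots=nk)
            key = tuple((c.kind, c.shape, c.rate) for c in g.components)
            if key not in seen:
                seen.add(key)
                grids.append(g)
    return grids


def bootstrap_select_model(
    counts_for_otu,
    t,
    candidate_grids: list[ComponentGrid] | None = None,
    B: int = 50,
    rng: np.random.Generator | int | None = None,
) -> PopulationMixture:
    """Bootstrap model selection and weight averaging.

    For each of B bootstrap resamples of subjects, every candidate grid is fit
    to the resampled spectrum; the grid with the smallest mean objective wins
    (ties broken toward fewer components) and its bootstrap weight vectors are
    averaged and renormalised into the final population weights.
    """
    counts = np.asarray(counts_for_otu)
    t = np.asarray(t, dtype=float)
    if candidate_grids is None:
        candidate_grids = default_candidate_grids(counts)
    if not candidate_grids:
        raise ValueError("no candidate grids")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    I = counts.size

    tensors = [component_pmf_tensor(g, t) for g in candidate_grids]
    objectives = np.zeros((len(candidate_grids), B))
    weight_draws: list[list[np.ndarray]] = [[] for _ in candidate_grids]
    for b in range(B):
        idx = rng.integers(0, I, size=I)
        for gi, (grid, tensor) in enumerate(zip(candidate_grids, tensors)):
            y = aggregate_counts(counts[idx], grid.cutoff)
            A = I * _design_matrix(tensor[:, :, idx])
            w, obj = simplex_lstsq(A, y)
            objectives[gi, b] = obj
            weight_draws[gi].append(w)
    mean_obj = objectives.mean(axis=1)
    order = sorted(
        range(len(candidate_grids)),
        key=lambda gi: (mean_obj[gi], candidate_grids[gi].n_components),
    )
    best = order[0]
    grid = candidate_grids[best]
    w = np.mean(weight_draws[best], axis=0)
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    y_full = aggregate_counts(counts, grid.cutoff)
    A_full = I * _design_matrix(tensors[best])
    resid = A_full @ w - y_full
    return PopulationMixture(
        grid=grid,
        weights=w,
        objective=float(resid @ resid),
        n_bootstrap=B,
        selection={
            "mean_objectives": mean_obj.tolist(),
            "selected": best,
            "n_candidates": len(candidate_grids),
        },
    )


def category_matrix(grid: ComponentGrid, t, pmf_tensor: np.ndarray | None = None) -> np.ndarray:
    """Shared component-by-category probability matrix over (z, 0..C, h).

    Gamma rows carry the population-averaged count probabilities (the same
    averages used in fitting); the zero point mass is the z indicator and the
    high point mass the tail indicator, so every row sums to 1.
    """
    if pmf_tensor is None:
        pmf_tensor = component_pmf_tensor(grid, t)
    pbar = pmf_tensor.mean(axis=2)  # (M, C+1)
    M = grid.n_components
    P = np.zeros((M, grid.n_categories))
    for m, comp in enumerate(grid.components):
        if comp.kind == ZERO:
            P[m, 0] = 1.0
        elif comp.kind == HIGH:
            P[m, -1] = 1.0
        else:
            P[m, 1:-1] = pbar[m]
            P[m, -1] = max(0.0, 1.0 - pbar[m].sum())
    return P


def posterior_weights(
    grid: ComponentGrid, population_weights, counts_for_otu, t
) -> np.ndarray:
    """(I, M) Bayes posterior component weights for every subject.

    The likelihood of component m at observation n_i is its pmf at n_i for
    n_i <= C and its tail mass P(K > C | t_i) for n_i > C; the zero point mass
    is compatible only with n_i = 0, the high point mass only with n_i > C.
    """
    counts = np.asarray(counts_for_otu)
    t = np.asarray(t, dtype=float)
    w = np.asarray(population_weights, dtype=float)
    I, M = counts.size, grid.n_components
    lik = np.zeros((I, M))
    tensor = component_pmf_tensor(grid, t)  # (M, C+1, I)
    tail = np.clip(1.0 - tensor.sum(axis=1), 0.0, 1.0)  # (M, I)
    over = counts > grid.cutoff
    k_idx = np.minimum(counts, grid.cutoff)
    lik = tensor[:, k_idx, np.arange(I)].T  # (I, M): pmf at each subject's count
    lik[over] = tail[:, over].T
    post = lik * w[None, :]
    norms = post.sum(axis=1)
    if (norms <= 0).any():
        bad = int(np.flatnonzero(norms <= 0)[0])
        raise ValueError(
            f"subject {bad}: no mixture component is compatible with count "
            f"{counts[bad]} under the estimated weights"
        )
    return post / norms[:, None]


def subject_mixture(
    grid: ComponentGrid,
    population: PopulationMixture,
    n_i: int,
    t_i: float,
    cat_matrix: np.ndarray | None = None,
    t_all=None,
    subject=None,
) -> SubjectMixture:
    """Posterior mixture for a single subject.

    ``cat_matrix`` (the shared category matrix) may be precomputed; otherwise
    it is built from ``t_all`` (defaults to the single subject's t_i).
    """
    if cat_matrix is None:
        cat_matrix = category_matrix(grid, np.atleast_1d(t_all if t_all is not None else t_i))
    w_i = posterior_weights(grid, population.weights, np.atleast_1d(n_i), np.atleast_1d(t_i))[0]
    pdf = w_i @ cat_matrix
    pdf = pdf / pdf.sum()
    cdf = np.cumsum(pdf)
    cdf[-1] = 1.0  # guard rounding in the final category
    return SubjectMixture(subject=subject, weights=w_i, category_pdf=pdf, category_cdf=cdf)
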