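"""End-to-end clustering pipeline and replicated simulation studies.

The mixture route per dataset: per-sample relative resolutions, per-OTU
bootstrap model selection and weight estimation, subject posterior mixtures,
per-OTU L2 distances combined across OTUs, a PAM sweep over K, and internal-
index selection of the final partition.  Baseline routes convert to relative
abundance (optionally log-transformed) and apply a classical beta-diversity
metric.  Study runs replicate the whole procedure over seeded simulations and
summarise mean accuracy, mean Jaccard index and mean selected K per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from . import distances as dist
from . import mixture as mx
from .io import LabelVector, OtuCountTable, to_relative_abundance
from .pam import ClusteringResult, pam_sweep
from .simulate import SimulationConfig, simulate_dataset, simulate_tree
from .validation import matched_accuracy, score_index, select_k

MIXTURE_METRICS = ("l2-d-pdf", "l2-d-cdf", "l2-c-cdf")
BASELINE_METRICS = ("manhattan", "euclidean", "bray-curtis", "wunifrac", "gunifrac")
ALL_METRICS = MIXTURE_METRICS + BASELINE_METRICS


@dataclass
class PipelineOptions:
    metric: str = "l2-d-pdf"
    k_range: tuple[int, int] = (2, 10)
    index: str = "dunn"
    combine: str = "l2"
    log_transform: bool = False
    epsilon: float = dist.EPSILON
    unifrac_alpha: float = 0.5
    cutoff_quantile: float = 0.99
    c_mid_values: tuple[int, ...] = (5, 10)
    knot_values: tuple[int, ...] = (3, 5)
    n_bootstrap: int = 50
    seed: int | None = None
    tree: object = None


@dataclass
class ClusteringOutput:
    result: ClusteringResult
    sweep: list[ClusteringResult]
    index_scores: dict[int, float]
    distance_matrix: object
    metric: str


def mixture_distance_matrices(
    table: OtuCountTable,
    metrics=MIXTURE_METRICS,
    options: PipelineOptions | None = None,
) -> dict[str, object]:
    """Fit per-OTU mixtures once and return the requested L2 distance matrices."""
    options = options or PipelineOptions()
    t = mx.compute_relative_resolution(table.sample_totals, zero_total="floor")
    rng = np.random.default_rng(options.seed)
    sq_acc = {m: None for m in metrics}
    ids = list(map(str, table.sample_ids))
    for j in range(table.n_otus):
        counts = table.counts[:, j]
        if (counts > 0).sum() == 0:
            continue  # uninformative OTU: identical mixtures for everyone
        grids = mx.default_candidate_grids(
            counts,
            cutoff_quantile=options.cutoff_quantile,
            c_mid_values=options.c_mid_values,
            knot_values=options.knot_values,
        )
        pop = mx.bootstrap_select_model(
            counts, t, candidate_grids=grids, B=options.n_bootstrap, rng=rng
        )
        tensor = mx.component_pmf_tensor(pop.grid, t)
        cat = mx.category_matrix(pop.grid, t, pmf_tensor=tensor)
        W = mx.posterior_weights(pop.grid, pop.weights, counts, t)
        for m in metrics:
            if m == "l2-d-pdf":
                feats = W @ cat
            elif m == "l2-d-cdf":
                feats = np.cumsum(W @ cat, axis=1)
            elif m == "l2-c-cdf":
                feats = W @ dist.cdf_step_matrix(pop.grid, cat)
            else:
                raise ValueError(f"not a mixture metric: {m!r}")
            if options.combine == "l2":
                acc = squareform(pdist(feats, metric="sqeuclidean"))
            else:  # sum / mean accumulate plain distances
                acc = squareform(pdist(feats, metric="euclidean"))
            sq_acc[m] = acc if sq_acc[m] is None else sq_acc[m] + acc
    out = {}
    n_used = table.n_otus
    for m in metrics:
        if sq_acc[m] is None:
            raise ValueError("no OTU had positive counts")
        if options.combine == "l2":
            vals = np.sqrt(sq_acc[m])
        elif options.combine == "sum":
            vals = sq_acc[m]
        elif options.combine == "mean":
            vals = sq_acc[m] / n_used
        else:
            raise ValueError(f"unknown combination rule {options.combine!r}")
        out[m] = dist._as_dm(vals, ids)
    return out


def baseline_distance_matrix(table: OtuCountTable, metric: str, options: PipelineOptions):
    rel = to_relative_abundance(table)
    if metric in ("manhattan", "euclidean", "bray-curtis") and options.log_transform:
        rel = dist.log_transform(rel, pseudo=options.epsilon)
    if metric == "manhattan":
        return dist.manhattan(rel)
    if metric == "euclidean":
        return dist.euclidean(rel)
    if metric == "bray-curtis":
        return dist.bray_curtis(rel, epsilon=options.epsilon)
    if metric in ("wunifrac", "gunifrac"):
        if options.tree is None:
            raise ValueError(f"metric {metric!r}: tree required")
        if metric == "wunifrac":
            return dist.weighted_unifrac(rel, options.tree, epsilon=options.epsilon)
        return dist.generalized_unifrac(
            rel, options.tree, alpha=options.unifrac_alpha, epsilon=options.epsilon
        )
    raise ValueError(f"unknown metric {metric!r}")


def cluster_distance_matrix(dm, options: PipelineOptions) -> ClusteringOutput:
    sweep = pam_sweep(dm, k_range=options.k_range, seed=options.seed)
    scores: dict[int, float] = {}
    usable = []
    for r in sweep:
        try:
            scores[r.K] = score_index(dm, r, options.index)
            usable.append(r)
        except ValueError:
            continue
    if not usable:
        raise ValueError("no K produced a defined index score")
    best = select_k(dm, usable, options.index)
    return ClusteringOutput(
        result=best, sweep=sweep, index_scores=scores, distance_matrix=dm, metric=options.metric
    )


def run_clustering(table: OtuCountTable, options: PipelineOptions | None = None) -> ClusteringOutput:
    """Algorithm: fit (if a mixture metric), compute distances, PAM sweep,
    internal-index selection."""
    options = options or PipelineOptions()
    if options.metric in MIXTURE_METRICS:
        dm = mixture_distance_matrices(table, metrics=(options.metric,), options=options)[
            options.metric
        ]
    else:
        dm = baseline_distance_matrix(table, options.metric, options)
    return cluster_distance_matrix(dm, options)


@dataclass
class StudySummary:
    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    n_replicates: int
    failures: dict = field(default_factory=dict)


def run_simulation_study(
    config: SimulationConfig,
    metrics=("l2-d-pdf",),
    n_replicates: int = 20,
    base_seed: int = 0,
    options: PipelineOptions | None = None,
) -> StudySummary:
    """Replicated study: per replicate, one simulated dataset scored by every
    metric; summarises mean accuracy (MA), mean Jaccard (MJI) and mean K."""
    options = options or PipelineOptions()
    rows = []
    failures: dict[str, int] = {}
    for r in range(n_replicates):
        seed = base_seed + r
        ds = simulate_dataset(config, seed=seed)
        rep_options = replace(options, seed=seed)
        mix_wanted = [m for m in metrics if m in MIXTURE_METRICS]
        dms = {}
        if mix_wanted:
            dms.update(
                mixture_distance_matrices(ds.table, metrics=tuple(mix_wanted), options=rep_options)
            )
        tree = None
        for m in metrics:
            if m in dms:
                dm = dms[m]
            else:
                if m in ("wunifrac", "gunifrac") and rep_options.tree is None:
                    if tree is None:
                        tree = simulate_tree(ds.table.otu_ids, rng=seed)
                    rep_options = replace(rep_options, tree=tree)
                dm = baseline_distance_matrix(ds.table, m, rep_options)
            try:
                out = cluster_distance_matrix(dm, replace(rep_options, metric=m))
            except ValueError:
                failures[m] = failures.get(m, 0) + 1
                continue
            ext = matched_accuracy(out.result.assignment, ds.truth.labels)
            rows.append(
                {
                    "replicate": r,
                    "metric": m,
                    "K": out.result.K,
                    "accuracy": ext.accuracy,
                    "jaccard": ext.jaccard,
                    "seed": seed,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("metric")
        .agg(
            MA=("accuracy", "mean"),
            MJI=("jaccard", "mean"),
            mean_K=("K", "mean"),
            n=("replicate", "count"),
        )
        .reset_index()
    )
    return StudySummary(
        per_replicate=per_rep, summary=summary, n_replicates=n_replicates, failures=failures
    )


def differential_otus(table: OtuCountTable, assignment) -> pd.DataFrame:
    """Rank OTUs by between-cluster rank-sum tests on relative abundance with
    Benjamini-Hochberg correction; reports per-cluster mean (sd) and median
    (min, max) summaries."""
    a = np.asarray(assignment)
    labels = np.unique(a)
    if labels.size != 2:
        raise ValueError("differential OTU report requires exactly 2 clusters")
    g1 = np.flatnonzero(a == labels[0])
    g2 = np.flatnonzero(a == labels[1])
    if min(g1.size, g2.size) < 2:
        raise ValueError("each cluster needs at least 2 samples")
    rel = to_relative_abundance(table).values
    stats, pvals = [], []
    for j in range(table.n_otus):
        s, p = ranksums(rel[g1, j], rel[g2, j])
        stats.append(s)
        pvals.append(p)
    adj = multipletests(pvals, method="fdr_bh")[1]
    rows = []
    raw = table.counts
    for j, otu in enumerate(table.otu_ids):
        rows.append(
            {
                "otu": otu,
                "statistic": stats[j],
                "p_value": pvals[j],
                "p_adjusted": adj[j],
                "cluster1_mean": raw[g1, j].mean(),
                "cluster1_sd": raw[g1, j].std(ddof=1),
                "cluster1_median": float(np.median(raw[g1, j])),
                "cluster1_min": int(raw[g1, j].min()),
                "cluster1_max": int(raw[g1, j].max()),
                "cluster2_mean": raw[g2, j].mean(),
                "cluster2_sd": raw[g2, j].std(ddof=1),
                "cluster2_median": float(np.median(raw[g2, j])),
                "cluster2_min": int(raw[g2, j].min()),
                "cluster2_max": int(raw[g2, j].max()),
            }
        )
    df = pd.DataFrame(rows).sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    return df
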