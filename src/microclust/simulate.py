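"""Synthetic OTU count data with sub-class structure and controlled sparsity.

Each OTU is generated independently per sub-class: a zero proportion z_c is
drawn from a tier-specific Beta distribution (low / medium / high sparsity
tiers target realized zero fractions of 13-27%, 39-61% and 84-93%), a mixture
of a zero point mass (weight z_c) and M-1 Gamma rate components (M uniform on
5..15) is drawn, subjects are allocated to components multinomially, each
subject draws a latent rate r_i from its component and a relative resolution
t_i ~ Uniform(2/3, 4/3), and the observed count is Poisson(r_i * t_i).
Per-OTU rejection resampling keeps the realized zero fraction inside the
tier's interval.  Sub-classes are separable because their mixtures are drawn
independently.

A random bifurcating tree generator supplies phylogenies for the UniFrac
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import LabelVector, OtuCountTable

ZP_TIERS = {
    "low": {"interval": (0.13, 0.27)},
    "medium": {"interval": (0.39, 0.61)},
    "high": {"interval": (0.84, 0.93)},
}

# Mean fraction of *sampling* zeros contributed by the Gamma part of a random
# generator mixture (Monte-Carlo estimate, frozen); used to back out structural
# zero-mass targets from the realized-ZP tier intervals.
_SAMPLING_ZERO_INFLATION = 0.083

# Beta concentration (alpha_c + beta_c) for the per-subclass zero proportions.
_BETA_CONCENTRATION = 100.0


def subclass_beta_params(zp_tier: str, n_subclasses: int) -> list[tuple[float, float]]:
    """Per-subclass Beta(alpha_c, beta_c) for the structural zero proportion.

    The tier's zero-proportion interval applies to the *realized* zero
    fraction; subclass target means are spaced evenly inside it and corrected
    for the expected sampling-zero inflation, so varying alpha_c across
    subclasses is what makes them separable (every OTU shifts its zero
    fraction in the same direction).
    """
    lo, hi = ZP_TIERS[zp_tier]["interval"]
    g = _SAMPLING_ZERO_INFLATION
    params = []
    for c in range(n_subclasses):
        target = lo + (c + 0.5) * (hi - lo) / n_subclasses
        z_mean = np.clip((target - g) / (1.0 - g), 0.01, 0.99)
        params.append((_BETA_CONCENTRATION * z_mean, _BETA_CONCENTRATION * (1.0 - z_mean)))
    return params


@dataclass
class SimulationConfig:
    n_subclasses: int = 2
    subclass_size: int = 200
    n_otus: int = 25
    zp_tier: str = "high"
    m_range: tuple[int, int] = (5, 15)
    resolution_range: tuple[float, float] = (2.0 / 3.0, 4.0 / 3.0)
    mean_range: tuple[float, float] = (1.0, 150.0)
    shape_choices: tuple[int, ...] = (1, 2, 3, 4, 5)
    max_rejections: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subclasses < 1 or self.subclass_size < 1 or self.n_otus < 1:
            raise ValueError("sizes must be positive")
        if self.zp_tier not in ZP_TIERS:
            raise ValueError(f"zp_tier must be one of {sorted(ZP_TIERS)}")


@dataclass
class SimulatedDataset:
    table: OtuCountTable
    truth: LabelVector
    resolutions: np.ndarray  # drawn t_i per subject
    generating: list[list[dict]]  # [otu][subclass] generating mixture records
    realized_zero_proportions: np.ndarray  # per OTU

    @property
    def config(self) -> SimulationConfig:
        return self._config

    _config: SimulationConfig = field(default=None, repr=False)


def _draw_subclass_mixture(
    config: SimulationConfig, beta_params: tuple[float, float], rng: np.random.Generator
) -> dict:
    """One sub-class's generating mixture for one OTU."""
    a, b = beta_params
    z = rng.beta(a, b)
    M = int(rng.integers(config.m_range[0], config.m_range[1] + 1))
    lo, hi = np.log(config.mean_range[0]), np.log(config.mean_range[1])
    means = np.exp(rng.uniform(lo, hi, size=M - 1))
    shapes = rng.choice(config.shape_choices, size=M - 1).astype(float)
    rates = shapes / means
    gamma_w = rng.dirichlet(np.ones(M - 1)) * (1.0 - z)
    return {
        "zero_weight": float(z),
        "shapes": shapes,
        "rates": rates,
        "weights": np.concatenate([[z], gamma_w]),
    }


def _sample_counts(mix: dict, t: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Subject counts and component allocations for one sub-class of one OTU."""
    n = t.size
    comp = rng.choice(mix["weights"].size, size=n, p=mix["weights"])
    rates = np.zeros(n)
    pos = comp > 0
    if pos.any():
        shapes = mix["shapes"][comp[pos] - 1]
        betas = mix["rates"][comp[pos] - 1]
        rates[pos] = rng.gamma(shape=shapes, scale=1.0 / betas)
    counts = rng.poisson(rates * t)
    return counts, comp


def simulate_otu(
    config: SimulationConfig,
    t_by_subclass: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict], float]:
    """Generate one OTU across all sub-classes, rejection-resampling until the
    realized zero fraction lands inside the tier interval."""
    lo, hi = ZP_TIERS[config.zp_tier]["interval"]
    betas = subclass_beta_params(config.zp_tier, len(t_by_subclass))
    for _ in range(config.max_rejections):
        counts_parts, records = [], []
        for t_c, bp in zip(t_by_subclass, betas):
            mix = _draw_subclass_mixture(config, bp, rng)
            counts, comp = _sample_counts(mix, t_c, rng)
            mix = dict(mix, components_drawn=comp)
            counts_parts.append(counts)
            records.append(mix)
        counts = np.concatenate(counts_parts)
        zp = float((counts == 0).mean())
        if lo <= zp <= hi and (counts > 0).any():
            return counts, records, zp
    raise RuntimeError(
        f"could not realize a zero proportion in [{lo}, {hi}] within "
        f"{config.max_rejections} attempts; recalibrate the Beta parameters"
    )


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Full dataset: n_otus independent OTUs over all sub-classes."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n_total = config.n_subclasses * config.subclass_size
    t = rng.uniform(*config.resolution_range, size=n_total)
    t_by_subclass = [
        t[c * config.subclass_size : (c + 1) * config.subclass_size]
        for c in range(config.n_subclasses)
    ]
    counts = np.zeros((n_total, config.n_otus), dtype=np.int64)
    generating: list[list[dict]] = []
    zps = np.zeros(config.n_otus)
    for j in range(config.n_otus):
        cj, records, zp = simulate_otu(config, t_by_subclass, rng)
        counts[:, j] = cj
        generating.append(records)
        zps[j] = zp
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    otu_ids = [f"OTU{j:03d}" for j in range(config.n_otus)]
    labels = np.repeat(np.arange(1, config.n_subclasses + 1), config.subclass_size)
    ds = SimulatedDataset(
        table=OtuCountTable(sample_ids, otu_ids, counts),
        truth=LabelVector(sample_ids, labels),
        resolutions=t,
        generating=generating,
        realized_zero_proportions=zps,
        _config=config,
    )
    return ds


def simulate_tree(otu_ids, rng: np.random.Generator | int | None = None) -> TreeNode:
    """Random rooted bifurcating tree over the OTUs by sequential random
    joins, with Exponential(mean 1) branch lengths."""
    rng = np.random.default_rng(rng)
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    nodes = [TreeNode(name=o, length=float(rng.exponential(1.0))) for o in otu_ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return root
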