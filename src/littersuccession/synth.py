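"""Synthetic communities with known ground truth.

Every generator emulates one statistical structure the downstream analyses
assume: Dirichlet-multinomial source habitats, sinks drawn from known convex
mixtures of sources plus an unknown pool, planted correlated ASV blocks for
the co-occurrence network, random bifurcating phylogenies, and communities
assembled under a neutral or an environmental-filtering regime on a known
tree. Ground truth travels in :class:`SyntheticTruth` so recovery can be
scored exactly.

Defaults reflect desk-scale but realistic amplicon data: sequencing depths
in the tens of thousands, a few hundred ASVs, and uneven (low-concentration
Dirichlet) compositions typical of 16S/ITS surveys.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ParameterError
from .io import FeatureTable, validate_metadata

DEFAULT_DEPTH = 20_000
DEFAULT_CONCENTRATION = 0.3  # uneven compositions, as in real ASV tables


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a synthetic data set."""

    seed: int
    mixing_proportions: dict[str, float] | None = None
    block_assignments: dict[str, int] | None = None
    regime: str | None = None
    optimal_env: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mixing_proportions is not None:
            total = sum(self.mixing_proportions.values())
            if abs(total - 1.0) > 1e-12:
                raise ParameterError(f"mixing proportions sum to {total}, not 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _taxon_names(n: int) -> list[str]:
    return [f"ASV{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# sources and sinks
# ---------------------------------------------------------------------------

def simulate_sources(
    n_sources: int,
    n_taxa: int,
    samples_per_source: int,
    dirichlet_concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 0,
    depth: int = DEFAULT_DEPTH,
    source_names: list[str] | None = None,
    altitude: float = 750.0,
) -> tuple[FeatureTable, pd.DataFrame, np.ndarray]:
    """Simulate source habitats with distinct Dirichlet compositions.

    Each source habitat receives one composition vector drawn from a
    symmetric Dirichlet; its samples are independent multinomial draws of
    size ``depth`` from that composition. Returns the feature table, the
    sample metadata (habitat per sample) and the true composition matrix
    (n_sources x n_taxa).
    """
    if n_sources < 1 or n_taxa < 2 or samples_per_source < 1:
        raise ParameterError("n_sources >= 1, n_taxa >= 2 and samples_per_source >= 1 required")
    if dirichlet_concentration <= 0:
        raise ParameterError("dirichlet_concentration must be positive")
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    if source_names is None:
        canonical = ["phyllosphere", "soil"]
        source_names = [
            canonical[k] if k < len(canonical) else f"source{k + 1}" for k in range(n_sources)
        ]
    if len(source_names) != n_sources:
        raise ParameterError("source_names length must equal n_sources")

    rng = np.random.default_rng(seed)
    taxa = _taxon_names(n_taxa)
    profiles = rng.dirichlet(np.full(n_taxa, dirichlet_concentration), size=n_sources)
    counts = np.zeros((n_taxa, n_sources * samples_per_source), dtype=np.int64)
    sample_ids, habitats = [], []
    j = 0
    for k, name in enumerate(source_names):
        for r in range(samples_per_source):
            counts[:, j] = rng.multinomial(depth, profiles[k])
            sample_ids.append(f"{name}_s{r + 1:02d}")
            habitats.append(name)
            j += 1
    table = FeatureTable(tuple(taxa), tuple(sample_ids), counts)
    meta = pd.DataFrame({"habitat": habitats, "altitude": altitude}, index=sample_ids)
    meta = validate_metadata(meta, habitats=set(habitats))
    return table, meta, profiles


def simulate_sink(
    source_profiles: np.ndarray,
    mixing_proportions: np.ndarray,
    unknown_profile: np.ndarray,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw one sink as a multinomial from a convex mixture of sources.

    ``mixing_proportions`` has length K+1: one weight per named source plus
    the trailing weight of the unknown pool. The sink model is exactly the
    convex-combination model the source-tracking estimator fits, so
    parameter recovery is a well-posed oracle.
    """
    profiles = np.atleast_2d(np.asarray(source_profiles, dtype=float))
    alpha = np.asarray(mixing_proportions, dtype=float)
    unknown = np.asarray(unknown_profile, dtype=float)
    k, n = profiles.shape
    if alpha.shape != (k + 1,):
        raise ParameterError(f"mixing_proportions must have length K+1 = {k + 1}")
    if unknown.shape != (n,):
        raise ParameterError("unknown_profile length must match the taxon dimension")
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    for vec, what in ((alpha, "mixing_proportions"), (unknown, "unknown_profile"), *((profiles[i], f"source profile {i}") for i in range(k))):
        if (vec < -1e-12).any():
            raise ParameterError(f"{what} has negative entries")
        if abs(vec.sum() - 1.0) > 1e-8:
            raise ParameterError(f"{what} sums to {vec.sum():.10f}, not 1 (tol 1e-8)")
    rng = np.random.default_rng(seed)
    p = alpha[:k] @ profiles + alpha[k] * unknown
    p = np.clip(p, 0, None)
    p /= p.sum()
    counts = rng.multinomial(depth, p)
    names = [f"source{i + 1}" for i in range(k)] + ["unknown"]
    mixing = {name: float(a) for name, a in zip(names, alpha)}
    # renormalize away float noise so the truth invariant holds exactly
    total = sum(mixing.values())
    mixing = {kk: v / total for kk, v in mixing.items()}
    return counts, SyntheticTruth(seed=seed, mixing_proportions=mixing)


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int = 0, branch_rate: float = 1.0) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths.

    Subtrees are joined pairwise in random order until one root remains;
    every branch gets an independent Exponential(rate) length, so lengths
    are strictly positive with probability one. Leaf names follow the
    ``ASV####`` scheme shared by the table generators.
    """
    if n_taxa < 2:
        raise ParameterError("n_taxa must be >= 2")
    if branch_rate <= 0:
        raise ParameterError("branch_rate must be positive")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in _taxon_names(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0 / branch_rate))
        right.length = float(rng.exponential(1.0 / branch_rate))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# correlated blocks
# ---------------------------------------------------------------------------

def simulate_correlated_blocks(
    n_taxa: int,
    block_sizes: list[int],
    within_block_correlation: float,
    n_samples: int,
    seed: int = 0,
    base_abundance: float = 200.0,
    sigma: float = 1.0,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Plant co-occurring ASV blocks via a shared latent Gaussian factor.

    Taxa in one block mix a common factor with idiosyncratic noise so that
    their latent Spearman correlation hits the requested value (a Gaussian
    copula: the latent Pearson r is ``2*sin(pi*rho_s/6)``). Counts are the
    rounded exponential of the latent log-abundance, which preserves ranks,
    so the planted rank correlation survives into the count table. Off-block
    taxa are independent.
    """
    if not (0 < within_block_correlation <= 1):
        raise ParameterError("within_block_correlation must be in (0, 1]")
    if sum(block_sizes) > n_taxa:
        raise ParameterError("sum of block sizes exceeds n_taxa")
    if min(block_sizes, default=1) < 1:
        raise ParameterError("block sizes must be positive")
    if n_samples < 4:
        raise ParameterError("n_samples must be >= 4 (correlation p-values undefined below)")

    rng = np.random.default_rng(seed)
    taxa = _taxon_names(n_taxa)
    r_latent = min(1.0, 2.0 * np.sin(np.pi * within_block_correlation / 6.0))
    loading = np.sqrt(r_latent)
    noise_sd = np.sqrt(1.0 - r_latent)

    z = rng.standard_normal((n_taxa, n_samples))  # idiosyncratic
    assignments: dict[str, int] = {}
    start = 0
    for b, size in enumerate(block_sizes):
        factor = rng.standard_normal(n_samples)
        for i in range(start, start + size):
            z[i] = loading * factor + noise_sd * z[i]
            assignments[taxa[i]] = b
        start += size

    mu = np.log(base_abundance) + 0.5 * rng.standard_normal(n_taxa)
    counts = np.rint(np.exp(mu[:, None] + sigma * z)).astype(np.int64)
    sample_ids = [f"sample_{j + 1:03d}" for j in range(n_samples)]
    table = FeatureTable(tuple(taxa), tuple(sample_ids), counts)
    return table, SyntheticTruth(seed=seed, block_assignments=assignments)


# ---------------------------------------------------------------------------
# assembly regimes
# ---------------------------------------------------------------------------

def evolve_trait(
    tree: TreeNode, seed: int = 0, rate: float = 1.0, conservation: float = 0.0
) -> dict[str, float]:
    """Brownian-motion trait on the tree (variance = rate * branch length).

    With ``conservation`` > 0 the walk runs only along the deep branches:
    every maximal clade whose tip-to-tip patristic diameter is at most
    ``conservation`` inherits its ancestor's value unchanged (niche
    conservatism below that phylogenetic scale). ``conservation = 0``
    recovers the plain tip-level Brownian walk.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_value = values[id(node.parent)]
        values[id(node)] = parent_value + rng.normal(0.0, np.sqrt(rate * (node.length or 0.0)))
    if conservation <= 0:
        return {tip.name: values[id(tip)] for tip in tree.tips()}

    diameter = _subtree_diameters(tree)
    traits: dict[str, float] = {}
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_tip() or diameter[id(node)] <= conservation:
            for tip in ([node] if node.is_tip() else node.tips()):
                traits[tip.name] = values[id(node)]
        else:
            stack.extend(node.children)
    return traits


def _subtree_diameters(tree: TreeNode) -> dict[int, float]:
    """Max within-subtree tip-to-tip patristic distance per node."""
    max_depth: dict[int, float] = {}
    diameter: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            max_depth[id(node)] = 0.0
            diameter[id(node)] = 0.0
        else:
            depths = [max_depth[id(c)] + (c.length or 0.0) for c in node.children]
            max_depth[id(node)] = max(depths)
            best = max(diameter[id(c)] for c in node.children)
            two = sorted(depths)[-2:]
            if len(two) == 2:
                best = max(best, two[0] + two[1])
            diameter[id(node)] = best
    return diameter


def _tip_distance_matrix(tree: TreeNode, leaves: list[str]) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=list(leaves))
    order = [dm.index(t) for t in leaves]
    return dm.data[np.ix_(order, order)].astype(float)


def simulate_selection_regime(
    tree: TreeNode,
    regime: str,
    n_communities: int,
    taxa_per_community: int,
    seed: int = 0,
    selection_width: float | None = None,
    pool_ratio: float = 1.6,
    conservation_quantile: float = 0.10,
    abundance_coupling: float = 2.0,
    abundance_noise: float = 0.1,
    mean_abundance: float = 100.0,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Communities assembled neutrally or under shared environmental filtering.

    ``neutral``: each community is a uniform random subset of the tree's
    leaves with independent lognormal abundances — no phylogenetic signal.

    ``filtering``: a niche trait evolves on the tree by a Brownian walk with
    conservatism below the ``conservation_quantile`` of tip-to-tip patristic
    distances (close relatives share a niche, as marker-gene ecology
    assumes). All communities share one environmental optimum, placed where
    the regional trait distribution is densest, and membership and abundance
    follow a Gaussian kernel in trait distance. The kernel width defaults to
    the value at which the effective selected pool is ``pool_ratio`` times
    the community richness, so communities are phylogenetically clustered
    around the same clades yet turn over taxa between samples — the
    signature homogeneous-selection classifiers must detect. Abundance is
    the kernel weight raised to ``abundance_coupling`` times lognormal noise
    of sigma ``abundance_noise``.
    """
    if regime not in ("neutral", "filtering"):
        raise ParameterError(f"unknown regime {regime!r}; expected 'neutral' or 'filtering'")
    leaves = [t.name for t in tree.tips()]
    if taxa_per_community > len(leaves):
        raise ParameterError("taxa_per_community exceeds the number of tree leaves")
    if n_communities < 1 or taxa_per_community < 2:
        raise ParameterError("need n_communities >= 1 and taxa_per_community >= 2")

    rng = np.random.default_rng(seed)
    n_taxa = len(leaves)
    counts = np.zeros((n_taxa, n_communities), dtype=np.int64)
    optimal_env = None
    noise_sigma = 0.5  # neutral: broad random abundances

    if regime == "filtering":
        dist = _tip_distance_matrix(tree, leaves)
        upper = dist[np.triu_indices(n_taxa, 1)]
        conservation = float(np.quantile(upper, conservation_quantile))
        traits = evolve_trait(tree, seed=int(rng.integers(2**31)), conservation=conservation)
        trait_vec = np.array([traits[name] for name in leaves])
        if selection_width is not None:
            width = max(float(selection_width), 1e-9)
            weights = _kernel_at_densest(trait_vec, width)
        else:
            width, weights = _adaptive_kernel(trait_vec, pool_ratio * taxa_per_community)
        optimal_env = {name: float(traits[name]) for name in leaves}
        noise_sigma = abundance_noise
    else:
        weights = np.ones(n_taxa)
        abundance_coupling = 1.0

    p = weights / weights.sum()
    for j in range(n_communities):
        members = rng.choice(n_taxa, size=taxa_per_community, replace=False, p=p)
        noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=taxa_per_community)
        relative = weights[members] / weights[members].mean()
        abundance = mean_abundance * noise * relative**abundance_coupling
        counts[members, j] = np.maximum(1, np.rint(abundance)).astype(np.int64)

    sample_ids = [f"comm_{j + 1:03d}" for j in range(n_communities)]
    table = FeatureTable(tuple(leaves), tuple(sample_ids), counts)
    truth = SyntheticTruth(seed=seed, regime=regime, optimal_env=optimal_env)
    return table, truth


def _kernel_at_densest(trait_vec: np.ndarray, width: float) -> np.ndarray:
    """Gaussian kernel weights with the optimum at the densest trait value."""
    density = [np.exp(-0.5 * ((trait_vec - t) / width) ** 2).sum() for t in trait_vec]
    optimum = float(trait_vec[int(np.argmax(density))])
    return np.exp(-0.5 * ((trait_vec - optimum) / width) ** 2) + 1e-12


def _adaptive_kernel(trait_vec: np.ndarray, target_pool: float) -> tuple[float, np.ndarray]:
    """Bisect the kernel width until the effective selected pool hits target.

    Pool size is measured as inverse Simpson concentration of the selection
    weights, so the selection strength is comparable across trait
    realizations.
    """
    spread = float(np.std(trait_vec))
    lo, hi = 1e-3 * spread, 5.0 * spread
    weights = _kernel_at_densest(trait_vec, hi)
    for _ in range(60):
        width = 0.5 * (lo + hi)
        weights = _kernel_at_densest(trait_vec, width)
        p = weights / weights.sum()
        pool = 1.0 / np.sum(p**2)
        if pool > target_pool:
            hi = width
        else:
            lo = width
    return 0.5 * (lo + hi), weights
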