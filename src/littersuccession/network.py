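"""Co-occurrence network, leave-one-out keystone scores and niche overlap.

The network connects the most abundant ASVs whose pairwise correlation
passes both a strict correlation threshold (|r| > 0.8 by default) and a
significance threshold (p < 0.01). Each node's importance is the
leave-one-out impact score: remove the node, recompute the mean degree,
mean betweenness and mean (harmonic) closeness of the remaining network,
and sum the absolute changes relative to the full network's means. The top
10% of impact scores are keystones; their origin is read off detection in
the phyllosphere and soil tables, and origin groups are compared with
Pianka's niche-overlap index over litter samples.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .io import FeatureTable

ORIGIN_LABELS = ("phyllosphere", "soil", "both", "unknown")


@dataclass
class CooccurrenceNetwork:
    """Undirected correlation graph over ASV ids.

    Edge attributes: ``r`` (correlation) and ``p`` (two-sided p-value).
    Isolated nodes stay in the node set.
    """

    graph: nx.Graph = field(repr=False)
    build_params: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "r": data["r"], "p": data["p"]}
            for a, b, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p"])


def _correlation_matrix(x: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise correlation and two-sided p (t-approximation) between rows."""
    m, n = x.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows yield nan r; dropped below
        if method == "spearman":
            if m == 2:
                r, p = stats.spearmanr(x[0], x[1])
                return np.array([[1.0, r], [r, 1.0]]), np.array([[0.0, p], [p, 0.0]])
            rho, p = stats.spearmanr(x.T)
            return np.asarray(rho), np.asarray(p)
        r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def build_network(
    table: FeatureTable,
    top_n: int = 400,
    method: str = "spearman",
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
) -> CooccurrenceNetwork:
    """Build the co-occurrence network over the ``top_n`` most abundant ASVs.

    Edges require |r| strictly greater than ``r_threshold`` and p strictly
    below ``p_threshold``. Abundance ties at the top-n cut are broken by
    taxon id.
    """
    if method not in ("spearman", "pearson"):
        raise ParameterError(f"unknown correlation method {method!r}")
    if top_n < 2:
        raise ParameterError("top_n must be >= 2")
    if not (0 < r_threshold < 1):
        raise ParameterError("r_threshold must be in (0, 1)")
    if not (0 < p_threshold <= 1):
        raise ParameterError("p_threshold must be in (0, 1]")
    n_samples = len(table.sample_ids)
    if n_samples < 4:
        raise InputError("need >= 4 samples for a defensible correlation p-value")

    totals = table.taxon_sums()
    ranked = sorted(range(len(table.taxon_ids)), key=lambda i: (-totals[i], table.taxon_ids[i]))
    keep = ranked[: min(top_n, len(ranked))]
    ids = [table.taxon_ids[i] for i in keep]
    x = table.counts[keep, :].astype(float)

    r, p = _correlation_matrix(x, method)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            rij, pij = r[i, j], p[i, j]
            if np.isfinite(rij) and abs(rij) > r_threshold and pij < p_threshold:
                graph.add_edge(ids[i], ids[j], r=float(rij), p=float(pij))
    params = {
        "top_n": top_n,
        "method": method,
        "r_threshold": r_threshold,
        "p_threshold": p_threshold,
        "n_samples": n_samples,
    }
    return CooccurrenceNetwork(graph=graph, build_params=params)


# ---------------------------------------------------------------------------
# centralities and leave-one-out impact
# ---------------------------------------------------------------------------

def centralities(net: CooccurrenceNetwork | nx.Graph) -> pd.DataFrame:
    """Degree, unnormalized betweenness and harmonic closeness per node.

    Harmonic closeness (sum of reciprocal shortest-path distances) stays
    defined when node removal disconnects the graph, which classic
    closeness does not.
    """
    graph = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if graph.number_of_nodes() == 0:
        raise InputError("empty network")
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.harmonic_centrality(graph)
    frame = pd.DataFrame(
        {"degree": degree, "betweenness": betweenness, "closeness": closeness}
    )
    frame.index.name = "node"
    return frame.sort_index()


def _mean_centralities(graph: nx.Graph) -> np.ndarray:
    frame = centralities(graph)
    return frame.to_numpy(dtype=float).mean(axis=0)


def loo_impact_scores(net: CooccurrenceNetwork | nx.Graph) -> pd.Series:
    """Leave-one-out impact score per node.

    I_v = |d mean degree| + |d mean betweenness| + |d mean closeness|
    between the full network and the network with v (and its edges)
    removed; means are over the nodes present in each graph, and the three
    terms are summed without rescaling.
    """
    graph = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if graph.number_of_nodes() < 3:
        raise InputError("leave-one-out impact needs >= 3 nodes")
    base = _mean_centralities(graph)
    scores = {}
    for node in graph.nodes:
        reduced = graph.copy()
        reduced.remove_node(node)
        scores[node] = float(np.abs(_mean_centralities(reduced) - base).sum())
    series = pd.Series(scores, name="impact")
    series.index.name = "node"
    return series.sort_index()


def identify_keystones(
    scores: pd.Series | dict,
    quantile: float = 0.90,
    degrees: pd.Series | dict | None = None,
) -> list[str]:
    """Top-(1 - quantile) impact scores; exactly ceil((1-q) * n) nodes.

    Ties at the cut are broken by larger degree, then lexicographic id, so
    the selection is deterministic and order-independent.
    """
    scores = pd.Series(scores)
    if scores.empty:
        raise InputError("no scores")
    if not (0 < quantile < 1):
        raise ParameterError("quantile must be in (0, 1)")
    k = math.ceil((1.0 - quantile) * len(scores))
    deg = pd.Series(degrees) if degrees is not None else pd.Series(0, index=scores.index)
    ranked = sorted(
        scores.index, key=lambda v: (-scores[v], -deg.get(v, 0), v)
    )
    return ranked[:k]


# ---------------------------------------------------------------------------
# origin classification and niche overlap
# ---------------------------------------------------------------------------

def classify_origin(
    keystones,
    phyllosphere_table: FeatureTable,
    soil_table: FeatureTable,
    min_count: int = 1,
) -> dict[str, str]:
    """Detection-based origin per keystone ASV.

    An ASV detected (total count >= min_count) only in phyllosphere samples
    is 'phyllosphere', only in soil 'soil', in both 'both', in neither
    'unknown'.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    phyllo_totals = dict(zip(phyllosphere_table.taxon_ids, phyllosphere_table.taxon_sums()))
    soil_totals = dict(zip(soil_table.taxon_ids, soil_table.taxon_sums()))
    out: dict[str, str] = {}
    for node in keystones:
        in_phyllo = phyllo_totals.get(node, 0) >= min_count
        in_soil = soil_totals.get(node, 0) >= min_count
        if in_phyllo and in_soil:
            out[node] = "both"
        elif in_phyllo:
            out[node] = "phyllosphere"
        elif in_soil:
            out[node] = "soil"
        else:
            out[node] = "unknown"
    return out


def _utilization(group, litter_table: FeatureTable) -> np.ndarray:
    rel = litter_table.relative_abundance()
    idx = litter_table.taxon_index()
    missing = [t for t in group if t not in idx]
    if missing:
        raise ParameterError(f"taxa not in litter table: {missing[:5]}")
    rows = [idx[t] for t in group]
    use = rel[rows, :].sum(axis=0)
    total = use.sum()
    if total <= 0:
        warnings.warn("group has zero abundance in every litter sample; overlap undefined",
                      stacklevel=3)
        return np.full(use.shape, np.nan)
    return use / total


def niche_overlap(
    group_a,
    group_b,
    litter_table: FeatureTable,
    index: str = "pianka",
) -> float:
    """Niche overlap between two taxon groups over litter samples.

    Resource states are the litter samples; each group's utilization
    distribution is its summed relative abundance per sample, normalized.
    ``pianka`` is the symmetric index O = sum(pq) / sqrt(sum(p^2) sum(q^2))
    in [0, 1]; ``levins`` is the asymmetric overlap of group A onto group B,
    sum(pq) / sum(q^2).
    """
    if index not in ("pianka", "levins"):
        raise ParameterError(f"unknown niche-overlap index {index!r}")
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    p = _utilization(group_a, litter_table)
    q = _utilization(group_b, litter_table)
    if np.isnan(p).any() or np.isnan(q).any():
        return float("nan")
    if index == "pianka":
        return float((p @ q) / np.sqrt((p @ p) * (q @ q)))
    return float((p @ q) / (q @ q))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def keystone_report(
    net: CooccurrenceNetwork,
    phyllosphere_table: FeatureTable | None = None,
    soil_table: FeatureTable | None = None,
    quantile: float = 0.90,
) -> pd.DataFrame:
    """Per-node centralities, impact score, keystone flag and origin label."""
    cent = centralities(net)
    impact = loo_impact_scores(net)
    keystones = identify_keystones(impact, quantile=quantile, degrees=cent["degree"])
    frame = cent.copy()
    frame["impact"] = impact
    frame["keystone"] = frame.index.isin(keystones)
    if phyllosphere_table is not None and soil_table is not None:
        origin = classify_origin(keystones, phyllosphere_table, soil_table)
        frame["origin"] = [origin.get(node, "") for node in frame.index]
    return frame
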