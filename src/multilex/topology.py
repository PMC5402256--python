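"""Layer topology: summary statistics, configuration-model nulls,
cross-layer degree correlations, edge overlap (multiplexity) and structural
reducibility.

The reducibility analysis follows the Von Neumann entropy approach for
multilayer networks: each layer is represented by a density matrix (the
combinatorial Laplacian normalized by its trace), layers are compared by the
quantum Jensen-Shannon divergence, merged agglomeratively, and each cut of
the dendrogram is scored by the relative-entropy quality against the fully
aggregated network.  A multiplex is *irreducible* when no merge improves the
quality over keeping all layers separate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import kendalltau

from .core import Layer, MultiplexNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "LayerStats",
    "NullEnsemble",
    "DegreeCorrelationMatrix",
    "OverlapMatrix",
    "ReducibilityResult",
    "layer_summary",
    "configuration_model_ensemble",
    "cross_layer_degree_correlation",
    "edge_overlap",
    "vn_entropy",
    "jensen_shannon_divergence",
    "reducibility_analysis",
]

_STAT_FIELDS = ("mean_degree", "mean_clustering", "assortativity", "conn_fraction", "mean_path_lcc")


@dataclass
class LayerStats:
    """Five summary statistics of a single layer.

    ``mean_degree`` and ``mean_clustering`` average over all N nodes (local
    clustering of degree-<2 nodes counts as 0); ``assortativity`` is the
    Pearson correlation of degrees at edge endpoints (None when undefined);
    ``conn_fraction`` is the share of nodes in the largest connected
    component and ``mean_path_lcc`` the mean shortest-path length within it.
    """

    mean_degree: float
    mean_clustering: float
    assortativity: Optional[float]
    conn_fraction: float
    mean_path_lcc: Optional[float]

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in _STAT_FIELDS}


def layer_summary(layer: Layer, n_nodes: int | None = None, vocab=None) -> LayerStats:
    """Summary statistics of one layer (vocab or n_nodes supplies isolated nodes)."""
    g = layer.to_networkx(vocab)
    if n_nodes is not None and g.number_of_nodes() < n_nodes:
        g.add_nodes_from(f"__iso{i}" for i in range(n_nodes - g.number_of_nodes()))
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("layer summary needs at least 2 nodes")
    mean_degree = 2.0 * g.number_of_edges() / n
    mean_clustering = nx.average_clustering(g) if g.number_of_edges() else 0.0
    if g.number_of_edges() >= 1:
        with np.errstate(all="ignore"):
            a = nx.degree_assortativity_coefficient(g)
        assortativity = None if (a is None or math.isnan(a)) else float(a)
    else:
        assortativity = None
    components = list(nx.connected_components(g))
    lcc = max(components, key=len)
    conn_fraction = len(lcc) / n
    if len(lcc) >= 2:
        mean_path = nx.average_shortest_path_length(g.subgraph(lcc))
    else:
        mean_path = None
    return LayerStats(mean_degree, mean_clustering, assortativity, conn_fraction, mean_path)


@dataclass
class NullEnsemble:
    """Degree-preserving randomizations of one layer with stat aggregates."""

    source_layer: str
    samples: list[Layer]
    stat_means: dict
    stat_sds: dict
    n_samples: int
    seed: int


def _randomize(layer: Layer, n_swaps_per_edge: int, rng: np.random.Generator) -> Layer:
    g = layer.to_networkx()
    m = g.number_of_edges()
    if m < 2:
        return Layer(layer.name, layer.edges)
    nswap = n_swaps_per_edge * m
    seed = int(rng.integers(0, 2**31 - 1))
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXException:
        # rigid degree sequences (e.g. stars) admit few or no swaps; the
        # partially swapped graph still has the exact degree sequence
        pass
    return Layer(layer.name, g.edges())


def configuration_model_ensemble(
    layer: Layer,
    n_samples: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
    vocab=None,
) -> NullEnsemble:
    """Null ensemble of degree-preserving double-edge-swap randomizations.

    Every sample is a simple graph with exactly the source degree sequence
    ("configuration model" in the degree-sequence-preserving sense).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if layer.n_edges < 2:
        logger.warning("layer %s has < 2 edges; null samples equal the source", layer.name)
    rng = np.random.default_rng(seed)
    samples = [_randomize(layer, n_swaps_per_edge, rng) for _ in range(n_samples)]
    stats = [layer_summary(s, vocab=vocab) for s in samples]
    means, sds = {}, {}
    for f in _STAT_FIELDS:
        vals = [getattr(s, f) for s in stats]
        clean = [v for v in vals if v is not None]
        means[f] = float(np.mean(clean)) if clean else None
        sds[f] = float(np.std(clean)) if clean else None
    return NullEnsemble(layer.name, samples, means, sds, n_samples, seed)


@dataclass
class DegreeCorrelationMatrix:
    layer_names: tuple[str, ...]
    tau: np.ndarray
    pvalues: np.ndarray


def cross_layer_degree_correlation(mln: MultiplexNetwork) -> DegreeCorrelationMatrix:
    """Pairwise Kendall tau-b between per-layer degree vectors.

    Words are matched across layers through the shared vocabulary; a constant
    degree vector yields NaN (undefined rank correlation).
    """
    if mln.n_layers < 2:
        raise ValueError("need at least 2 layers")
    ids = mln.vocabulary.ids
    degs = [np.array([layer.degree(w) for w in ids]) for layer in mln.layers]
    L = mln.n_layers
    tau = np.eye(L)
    pvals = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            if np.all(degs[i] == degs[i][0]) or np.all(degs[j] == degs[j][0]):
                t, p = np.nan, np.nan
            else:
                t, p = kendalltau(degs[i], degs[j])
            tau[i, j] = tau[j, i] = t
            pvals[i, j] = pvals[j, i] = p
    return DegreeCorrelationMatrix(mln.layer_names, tau, pvals)


@dataclass
class OverlapMatrix:
    layer_names: tuple[str, ...]
    observed: np.ndarray
    null_mean: Optional[np.ndarray] = None
    null_sd: Optional[np.ndarray] = None
    zscore: Optional[np.ndarray] = None


def _pairwise_overlap(e1: frozenset, e2: frozenset, normalization: str) -> float:
    if not e1 or not e2:
        return np.nan
    inter = len(e1 & e2)
    if normalization == "min":
        return inter / min(len(e1), len(e2))
    if normalization == "jaccard":
        return inter / len(e1 | e2)
    raise ValueError(f"unknown normalization {normalization!r}")


def edge_overlap(
    mln: MultiplexNetwork,
    nulls: Optional[dict[str, NullEnsemble]] = None,
    normalization: str = "min",
) -> OverlapMatrix:
    """Multiplexity: pairwise edge overlap, optionally against null ensembles.

    Observed overlap(i, j) = |E_i ∩ E_j| / min(|E_i|, |E_j|) (self-overlap 1;
    Jaccard available via ``normalization="jaccard"``).  With null ensembles,
    the same quantity is recomputed between paired null samples of the two
    layers and summarized as mean, sd and Z-score.
    """
    L = mln.n_layers
    obs = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(L):
            obs[i, j] = _pairwise_overlap(mln.layers[i].edges, mln.layers[j].edges, normalization)
    if nulls is None:
        return OverlapMatrix(mln.layer_names, obs)
    null_mean = np.full((L, L), np.nan)
    null_sd = np.full((L, L), np.nan)
    z = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(L):
            ni = nulls.get(mln.layers[i].name)
            nj = nulls.get(mln.layers[j].name)
            if ni is None or nj is None:
                continue
            k = min(len(ni.samples), len(nj.samples))
            vals = [
                _pairwise_overlap(ni.samples[s].edges, nj.samples[s].edges, normalization)
                for s in range(k)
            ]
            vals = [v for v in vals if not math.isnan(v)]
            if not vals:
                continue
            null_mean[i, j] = np.mean(vals)
            null_sd[i, j] = np.std(vals)
            if null_sd[i, j] > 0:
                z[i, j] = (obs[i, j] - null_mean[i, j]) / null_sd[i, j]
    return OverlapMatrix(mln.layer_names, obs, null_mean, null_sd, z)


# ---------------------------------------------------------------------------
# Structural reducibility


def _density_matrix(g: nx.Graph, nodelist: Sequence[str]) -> np.ndarray:
    lap = nx.laplacian_matrix(g, nodelist=nodelist, weight="weight").toarray().astype(float)
    tr = np.trace(lap)
    if tr <= 0:
        raise ValueError("layer with zero edges has no density matrix")
    return lap / tr


def vn_entropy(rho: np.ndarray) -> float:
    """Von Neumann entropy -sum(lambda log2 lambda) of a density matrix."""
    lam = np.linalg.eigvalsh(rho)
    lam = lam[lam > 1e-14]
    return float(-np.sum(lam * np.log2(lam)))


def jensen_shannon_divergence(rho1: np.ndarray, rho2: np.ndarray) -> float:
    """Quantum Jensen-Shannon divergence between two density matrices."""
    mix = 0.5 * (rho1 + rho2)
    jsd = vn_entropy(mix) - 0.5 * (vn_entropy(rho1) + vn_entropy(rho2))
    return max(0.0, jsd)


@dataclass
class ReducibilityResult:
    layer_names: tuple[str, ...]
    jsd: np.ndarray
    merge_sequence: list[tuple[frozenset, frozenset]]
    quality: list[float]  # quality[m] = quality after m merges (m=0: all layers apart)
    irreducible: bool
    partitions: list[list[frozenset]] = field(default_factory=list)
    notes: str = ""

    @property
    def verdict(self) -> str:
        return "irreducible" if self.irreducible else "reducible"

    def to_newick(self) -> str:
        """Merge dendrogram as a newick string (no branch lengths)."""
        labels: dict[frozenset, str] = {
            frozenset([i]): name for i, name in enumerate(self.layer_names)
        }
        for ga, gb in self.merge_sequence:
            labels[ga | gb] = f"({labels[ga]},{labels[gb]})"
        root = frozenset(range(len(self.layer_names)))
        return labels.get(root, ",".join(self.layer_names)) + ";"


def _group_density(layers_nx: list[nx.Graph], group: frozenset, nodelist) -> np.ndarray:
    # aggregation of a group = sum of adjacency matrices (multi-edges add weight)
    agg = nx.Graph()
    agg.add_nodes_from(nodelist)
    for idx in group:
        for u, v in layers_nx[idx].edges():
            w = agg[u][v]["weight"] + 1 if agg.has_edge(u, v) else 1
            agg.add_edge(u, v, weight=w)
    return _density_matrix(agg, nodelist)


def reducibility_analysis(mln: MultiplexNetwork) -> ReducibilityResult:
    """Decide whether layers can be aggregated without information loss.

    Computes pairwise quantum JSD between layer density matrices, builds a
    Ward-linkage dendrogram on sqrt(JSD) distances, and scores every cut by
    the relative-entropy quality

        q(partition) = 1 - mean_k h(rho_k) / h(rho_aggregate)

    where each rho_k aggregates one group of the partition.  The multiplex is
    irreducible iff the quality is strictly maximal at the no-merge cut.
    """
    L = mln.n_layers
    if L < 2:
        raise ValueError("reducibility needs at least 2 layers")
    for layer in mln.layers:
        if layer.n_edges == 0:
            raise ValueError(f"layer {layer.name!r} has no edges; entropy undefined")
    nodelist = list(mln.vocabulary.ids)
    layers_nx = [l.to_networkx(mln.vocabulary) for l in mln.layers]
    rhos = [_density_matrix(g, nodelist) for g in layers_nx]
    jsd = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            jsd[i, j] = jsd[j, i] = jensen_shannon_divergence(rhos[i], rhos[j])

    dist = np.sqrt(jsd)
    condensed = dist[np.triu_indices(L, k=1)]
    linkage = hierarchy.linkage(condensed, method="ward")

    # replay the linkage to enumerate partitions cut by cut
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(L)}
    partitions: list[list[frozenset]] = [list(clusters.values())]
    merge_sequence: list[tuple[frozenset, frozenset]] = []
    next_id = L
    active = dict(clusters)
    for a, b, _, _ in linkage:
        ga, gb = active.pop(int(a)), active.pop(int(b))
        merged = ga | gb
        merge_sequence.append((ga, gb))
        active[next_id] = merged
        next_id += 1
        partitions.append(list(active.values()))

    h_agg = vn_entropy(_group_density(layers_nx, frozenset(range(L)), nodelist))
    entropy_cache: dict[frozenset, float] = {}

    def group_entropy(group: frozenset) -> float:
        if group not in entropy_cache:
            if len(group) == 1:
                entropy_cache[group] = vn_entropy(rhos[next(iter(group))])
            else:
                entropy_cache[group] = vn_entropy(_group_density(layers_nx, group, nodelist))
        return entropy_cache[group]

    quality = []
    for part in partitions:
        mean_h = float(np.mean([group_entropy(g) for g in part]))
        quality.append(1.0 - mean_h / h_agg if h_agg > 0 else 0.0)

    irreducible = all(quality[0] > q for q in quality[1:])
    names = mln.layer_names
    return ReducibilityResult(names, jsd, merge_sequence, quality, irreducible, partitions)
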