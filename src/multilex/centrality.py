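"""Word scores from network centralities and word-specific attributes.

Every scorer returns a :class:`WordScoreTable` covering the whole
vocabulary, which downstream ranking turns into a predicted acquisition
trajectory.  Conventions:

* closeness is harmonic centrality normalized by N-1 (well defined on the
  fragmented single layers; unreachable pairs contribute 0); classic
  within-component closeness is available via ``variant="classic"``.
* betweenness is shortest-path betweenness computed and normalized per
  connected component.
* PageRank uses damping 0.85 and uniform teleport; isolated nodes receive
  teleport mass.
* multiplex variants run on the aggregate union graph: an edge is present if
  it exists on any layer and layer jumps are free; multiplex PageRank
  weights edges by their layer multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx

from .core import Layer, MultiplexNetwork, Vocabulary, aggregate, multidegree

__all__ = [
    "WordScoreTable",
    "layer_centrality",
    "multiplex_centrality",
    "attribute_score",
    "LAYER_METRICS",
    "MULTIPLEX_METRICS",
]

LAYER_METRICS = ("degree", "closeness", "betweenness", "pagerank", "clustering")
MULTIPLEX_METRICS = ("multidegree", "closeness", "betweenness", "pagerank")

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-10


@dataclass
class WordScoreTable:
    metric_name: str
    scope: str  # layer name, "multiplex", or "attribute"
    scores: dict[str, float]

    def __post_init__(self) -> None:
        for w, s in self.scores.items():
            if s != s or s in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite score for {w!r}")


def _graph_centrality(g: nx.Graph, metric: str, weight: str | None = None) -> dict[str, float]:
    n = g.number_of_nodes()
    if metric == "degree":
        return {v: float(d) for v, d in g.degree()}
    if metric == "closeness":
        h = nx.harmonic_centrality(g)
        return {v: h[v] / (n - 1) if n > 1 else 0.0 for v in g}
    if metric == "betweenness":
        scores = {v: 0.0 for v in g}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            scores.update(nx.betweenness_centrality(sub, normalized=True))
        return scores
    if metric == "pagerank":
        return nx.pagerank(
            g, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL, max_iter=1000, weight=weight
        )
    if metric == "clustering":
        return {v: float(c) for v, c in nx.clustering(g).items()}
    raise ValueError(f"unknown metric {metric!r}; choose from {LAYER_METRICS}")


def layer_centrality(
    layer: Layer,
    metric: str,
    vocab: Vocabulary,
    closeness_variant: str = "harmonic",
) -> WordScoreTable:
    """Centrality of every vocabulary word on a single layer."""
    g = layer.to_networkx(vocab)
    if metric == "closeness" and closeness_variant == "classic":
        scores = nx.closeness_centrality(g)  # within-component convention
    else:
        scores = _graph_centrality(g, metric)
    return WordScoreTable(metric, layer.name, {w: float(scores[w]) for w in vocab.ids})


def multiplex_centrality(mln: MultiplexNetwork, metric: str) -> WordScoreTable:
    """Centrality on the multiplex as a whole.

    Path-based metrics use the unweighted union of the layers (a path may
    switch relationship type at every hop at no cost); PageRank weights each
    union edge by the number of layers carrying it; multidegree sums
    per-layer degrees.
    """
    if metric == "multidegree":
        scores = {w: float(multidegree(mln, w)) for w in mln.vocabulary.ids}
        return WordScoreTable(metric, "multiplex", scores)
    g = aggregate(mln, weighted=True).to_networkx()
    weight = "weight" if metric == "pagerank" else None
    scores = _graph_centrality(g, metric, weight=weight)
    return WordScoreTable(metric, "multiplex", {w: float(scores[w]) for w in mln.vocabulary.ids})


def attribute_score(vocab: Vocabulary, attribute: str) -> WordScoreTable:
    """Word-specific (non-network) scores.

    ``frequency`` ranks frequent words first; ``neg_length`` scores words by
    minus their character count so that descending order puts short words
    first.
    """
    if attribute == "frequency":
        missing = [w.id for w in vocab if w.frequency is None]
        if missing:
            raise ValueError(f"words without frequency: {missing[:10]}")
        scores = {w.id: float(w.frequency) for w in vocab}
    elif attribute == "neg_length":
        missing = [w.id for w in vocab if w.length is None]
        if missing:
            raise ValueError(f"words without length: {missing[:10]}")
        scores = {w.id: -float(w.length) for w in vocab}
    else:
        raise ValueError(f"unknown attribute {attribute!r}")
    return WordScoreTable(attribute, "attribute", scores)
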