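"""Core data model for edge-coloured multiplex lexical networks.

A multiplex lexical network (MLN) is a set of undirected simple graphs
("layers") sharing one vocabulary of words.  Each layer encodes a different
word-word relationship (free association, feature sharing, co-occurrence in
child-directed speech, phonological similarity at edit distance one, or any
custom relation).  There are no inter-layer links: layer membership acts as
an edge colour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "Word",
    "Vocabulary",
    "Layer",
    "MultiplexNetwork",
    "AggregateGraph",
    "aggregate",
    "multidegree",
    "is_connected_multiplex",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge; rejects self-loops."""
    if u == v:
        raise ValueError(f"self-loop on {u!r} not allowed")
    return (u, v) if u < v else (v, u)


@dataclass
class Word:
    """A vocabulary item and its word-specific attributes.

    ``frequency`` is the occurrence count in child-directed speech,
    ``length`` the character count, ``ipa`` the phoneme-token transcription.
    All attributes except ``id`` are optional.
    """

    id: str
    frequency: Optional[float] = None
    length: Optional[int] = None
    ipa: Optional[tuple[str, ...]] = None
    pos_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("word id must be nonempty")
        if self.length is not None and self.length < 1:
            raise ValueError(f"word length must be >= 1, got {self.length}")
        if self.frequency is not None and self.frequency < 0:
            raise ValueError("word frequency must be nonnegative")
        if self.ipa is not None:
            self.ipa = tuple(self.ipa)


class Vocabulary:
    """Ordered collection of unique words; the shared node set of an MLN."""

    def __init__(self, words: Iterable[Word | str]):
        self._words: list[Word] = [
            w if isinstance(w, Word) else Word(w) for w in words
        ]
        self._index: dict[str, int] = {}
        for i, w in enumerate(self._words):
            if w.id in self._index:
                raise ValueError(f"duplicate word id {w.id!r}")
            self._index[w.id] = i
        if not self._words:
            raise ValueError("vocabulary must contain at least one word")

    @property
    def words(self) -> Sequence[Word]:
        return tuple(self._words)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(w.id for w in self._words)

    def __len__(self) -> int:
        return len(self._words)

    def __contains__(self, word_id: str) -> bool:
        return word_id in self._index

    def __iter__(self) -> Iterator[Word]:
        return iter(self._words)

    def __getitem__(self, word_id: str) -> Word:
        return self._words[self._index[word_id]]

    def index(self, word_id: str) -> int:
        return self._index[word_id]

    def subset(self, keep: Iterable[str]) -> "Vocabulary":
        """New vocabulary with the original order, restricted to ``keep``."""
        keep = set(keep)
        return Vocabulary([w for w in self._words if w.id in keep])


class Layer:
    """One relationship type: an undirected simple graph stored as an edge set.

    Edges are canonical unordered pairs of word ids.  Degrees are cached and
    the cache is invalidated on mutation; all metrics are pure functions of
    the stored edge set.
    """

    def __init__(self, name: str, edges: Iterable[tuple[str, str]] = ()):
        self.name = name
        self._edges: set[tuple[str, str]] = {canonical_edge(u, v) for u, v in edges}
        self._degree_cache: Optional[dict[str, int]] = None

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def add_edge(self, u: str, v: str) -> None:
        self._edges.add(canonical_edge(u, v))
        self._degree_cache = None

    def remove_edge(self, u: str, v: str) -> None:
        self._edges.discard(canonical_edge(u, v))
        self._degree_cache = None

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_edge(u, v) in self._edges

    def degree(self, word_id: str) -> int:
        if self._degree_cache is None:
            cache: dict[str, int] = {}
            for u, v in self._edges:
                cache[u] = cache.get(u, 0) + 1
                cache[v] = cache.get(v, 0) + 1
            self._degree_cache = cache
        return self._degree_cache.get(word_id, 0)

    def induced(self, keep: Iterable[str]) -> "Layer":
        keep = set(keep)
        return Layer(self.name, (e for e in self._edges if e[0] in keep and e[1] in keep))

    def to_networkx(self, vocab: Optional[Vocabulary] = None) -> nx.Graph:
        """As a networkx graph; with ``vocab``, isolated words are included."""
        g = nx.Graph(name=self.name)
        if vocab is not None:
            g.add_nodes_from(vocab.ids)
        g.add_edges_from(self._edges)
        return g

    def __repr__(self) -> str:
        return f"Layer({self.name!r}, {len(self._edges)} edges)"


class MultiplexNetwork:
    """Edge-coloured multiplex: one vocabulary, an ordered list of layers."""

    def __init__(self, vocabulary: Vocabulary, layers: Sequence[Layer]):
        if not layers:
            raise ValueError("a multiplex needs at least one layer")
        names = [layer.name for layer in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"layer names must be unique, got {names}")
        for layer in layers:
            for u, v in layer.edges:
                if u not in vocabulary or v not in vocabulary:
                    raise ValueError(
                        f"layer {layer.name!r} edge ({u!r}, {v!r}) leaves the vocabulary"
                    )
        self.vocabulary = vocabulary
        self.layers = list(layers)

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"no layer named {name!r}")

    def induced(self, keep: Iterable[str]) -> "MultiplexNetwork":
        keep = set(keep)
        return MultiplexNetwork(
            self.vocabulary.subset(keep), [l.induced(keep) for l in self.layers]
        )

    def __repr__(self) -> str:
        return (
            f"MultiplexNetwork(N={len(self.vocabulary)}, "
            f"layers={list(self.layer_names)})"
        )


@dataclass
class AggregateGraph:
    """Union of the layers; ``multiplicity`` maps each edge to the number of
    layers carrying it (all 1 when built unweighted)."""

    multiplicity: Mapping[tuple[str, str], int]
    vocabulary: Vocabulary
    weighted: bool = field(default=True)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.multiplicity)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vocabulary.ids)
        for (u, v), m in self.multiplicity.items():
            g.add_edge(u, v, weight=m)
        return g


def aggregate(mln: MultiplexNetwork, weighted: bool = True) -> AggregateGraph:
    """Union of the layer edge sets.

    With ``weighted=True`` each edge carries the number of layers containing
    it (its multiplicity); otherwise all multiplicities are 1.
    """
    mult: dict[tuple[str, str], int] = {}
    for layer in mln.layers:
        for e in layer.edges:
            mult[e] = mult.get(e, 0) + 1
    if not weighted:
        mult = {e: 1 for e in mult}
    return AggregateGraph(mult, mln.vocabulary, weighted=weighted)


def multidegree(mln: MultiplexNetwork, word_id: str) -> int:
    """Sum of a word's degrees over all layers."""
    if word_id not in mln.vocabulary:
        raise KeyError(f"unknown word id {word_id!r}")
    return sum(layer.degree(word_id) for layer in mln.layers)


def is_connected_multiplex(mln: MultiplexNetwork) -> bool:
    """True iff the (unweighted) aggregate graph is connected over all words.

    A pair of words may be linked by a path that switches relationship type
    at every hop; connectivity of the union is what "the multiplex is
    connected" means for an edge-coloured multiplex.
    """
    g = aggregate(mln, weighted=False).to_networkx()
    return nx.is_connected(g) if len(g) > 0 else False
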