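"""Build the four lexical layers from raw relational records.

Layer recipes:

* association  — undirected edge (A, B) iff B was produced as a free
  associate of cue A (or vice versa); strengths are read but ignored.
* feature      — edge iff two words share at least one semantic feature.
* cooccurrence — edge iff the pair's co-occurrence count in child-directed
  speech exceeds a threshold (default 45, strict ``>``).
* phonological — edge iff the IPA phoneme-token transcriptions are at
  Levenshtein distance exactly one.

The final vocabulary is the intersection of a CDI word list with the set of
words connected on at least one layer, iterated to a fixed point because
removing words can isolate others.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core import Layer, MultiplexNetwork, Vocabulary, Word, canonical_edge

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "FeatureRecord",
    "CooccurrenceRecord",
    "normalize_word",
    "build_association_layer",
    "build_feature_layer",
    "build_cooccurrence_layer",
    "ipa_edit_distance",
    "build_phonological_layer",
    "intersect_vocabulary",
    "count_cooccurrences",
]

DEFAULT_COOCCURRENCE_THRESHOLD = 45


@dataclass(frozen=True)
class AssociationRecord:
    cue: str
    target: str
    strength: Optional[float] = None


@dataclass(frozen=True)
class FeatureRecord:
    word: str
    feature: str

    def __post_init__(self) -> None:
        if not self.feature:
            raise ValueError("feature label must be nonempty")


@dataclass(frozen=True)
class CooccurrenceRecord:
    word1: str
    word2: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"co-occurrence count must be >= 0, got {self.count}")


def normalize_word(raw: str) -> str:
    """Ingest normalization: case-fold and join multiword labels with '_'.

    CDI items like "play dough" become one node id ("play_dough").  The rule
    is a convention of this package, applied uniformly at every reader.
    """
    return "_".join(raw.strip().casefold().split())


def _drop_foreign(pairs: Iterable[tuple[str, str]], vocab: Vocabulary, what: str):
    kept, dropped = [], 0
    for u, v in pairs:
        if u in vocab and v in vocab:
            kept.append((u, v))
        else:
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d records outside the vocabulary", what, dropped)
    return kept


def build_association_layer(
    records: Iterable[AssociationRecord], vocab: Vocabulary, name: str = "association"
) -> Layer:
    """Symmetrize cue→target free-association records into an undirected layer."""
    records = list(records)
    if not records:
        logger.warning("association layer built from an empty record set")
    pairs = _drop_foreign(
        ((r.cue, r.target) for r in records if r.cue != r.target), vocab, "association"
    )
    return Layer(name, pairs)


def build_feature_layer(
    records: Iterable[FeatureRecord], vocab: Vocabulary, name: str = "feature"
) -> Layer:
    """Connect words sharing at least one feature (one-mode projection of the
    word-feature bipartite graph with unit threshold)."""
    by_feature: dict[str, set[str]] = defaultdict(set)
    dropped = 0
    for r in records:
        if r.word in vocab:
            by_feature[r.feature].add(r.word)
        else:
            dropped += 1
    if dropped:
        logger.info("feature layer: dropped %d records outside the vocabulary", dropped)
    edges = set()
    for members in by_feature.values():
        for u, v in itertools.combinations(sorted(members), 2):
            edges.add((u, v))
    return Layer(name, edges)


def build_cooccurrence_layer(
    records: Iterable[CooccurrenceRecord],
    vocab: Vocabulary,
    threshold: int = DEFAULT_COOCCURRENCE_THRESHOLD,
    name: str = "cooccurrence",
) -> Layer:
    """Keep pairs whose count strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    # pair counts may arrive split across records; sum before thresholding
    totals: Counter[tuple[str, str]] = Counter()
    for r in records:
        if r.word1 == r.word2:
            continue
        totals[canonical_edge(r.word1, r.word2)] += r.count
    pairs = [e for e, c in totals.items() if c > threshold]
    return Layer(name, _drop_foreign(pairs, vocab, "cooccurrence"))


def ipa_edit_distance(s1: Sequence[str], s2: Sequence[str]) -> int:
    """Levenshtein distance between phoneme-token sequences.

    Unit-cost insertions, deletions and substitutions over whole phoneme
    tokens (so [t, ʃ] vs [tʃ] counts two tokens against one, by design).
    """
    if len(s1) < len(s2):
        s1, s2 = s2, s1
    prev = list(range(len(s2) + 1))
    for i, a in enumerate(s1, start=1):
        cur = [i]
        for j, b in enumerate(s2, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


def build_phonological_layer(
    lexicon: Mapping[str, Sequence[str]],
    vocab: Vocabulary,
    name: str = "phonological",
) -> Layer:
    """Connect words whose transcriptions are at edit distance exactly one.

    Words without a transcription stay isolated.  With multiple
    transcriptions per word, pass the preferred one (the readers keep the
    first listed).
    """
    items = [(w, tuple(lexicon[w])) for w in vocab.ids if w in lexicon]
    missing = len(vocab) - len(items)
    if missing:
        logger.info("phonological layer: %d words lack a transcription", missing)
    edges = []
    for (w1, t1), (w2, t2) in itertools.combinations(items, 2):
        if abs(len(t1) - len(t2)) > 1:
            continue
        if ipa_edit_distance(t1, t2) == 1:
            edges.append((w1, w2))
    return Layer(name, edges)


def intersect_vocabulary(
    cdi_words: Iterable[str], layers: Sequence[Layer], word_attrs: Optional[Mapping[str, Word]] = None
) -> MultiplexNetwork:
    """Restrict to CDI words with at least one connection on any layer.

    Re-induces the layers on the retained word set and iterates until stable,
    since removing a word can isolate its former neighbours.  Raises if the
    fixed point is empty.
    """
    keep = set(cdi_words)
    current = [l for l in layers]
    while True:
        connected = set()
        for layer in current:
            for u, v in layer.edges:
                connected.add(u)
                connected.add(v)
        new_keep = keep & connected
        if new_keep == keep and all(
            all(u in keep and v in keep for u, v in l.edges) for l in current
        ):
            break
        if not new_keep:
            counts = {l.name: l.n_edges for l in current}
            raise ValueError(
                f"empty vocabulary after intersection (layer edge counts: {counts})"
            )
        keep = new_keep
        current = [l.induced(keep) for l in current]
    words = [
        word_attrs[w] if word_attrs and w in word_attrs else Word(w)
        for w in sorted(keep)
    ]
    return MultiplexNetwork(Vocabulary(words), current)


def count_cooccurrences(utterances: Iterable[Sequence[str]]) -> list[CooccurrenceRecord]:
    """Adjacent-bigram co-occurrence counts over tokenized utterances.

    A convention of this package, not of any source corpus: each ordered
    adjacent pair within an utterance adds one count to its unordered pair.
    """
    totals: Counter[tuple[str, str]] = Counter()
    for utt in utterances:
        toks = [normalize_word(t) for t in utt]
        for a, b in zip(toks, toks[1:]):
            if a != b and a and b:
                totals[canonical_edge(a, b)] += 1
    return [CooccurrenceRecord(u, v, c) for (u, v), c in sorted(totals.items())]
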