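"""Build a tiny four-layer multiplex lexicon from raw relational records.

Free-association pairs, feature norms, co-occurrence counts and IPA
transcriptions are intersected with a CDI-style word list: only words with
at least one connection on some layer survive.
"""

from multilex.build import (
    AssociationRecord,
    CooccurrenceRecord,
    FeatureRecord,
    build_association_layer,
    build_cooccurrence_layer,
    build_feature_layer,
    build_phonological_layer,
    intersect_vocabulary,
)
from multilex.core import Vocabulary, is_connected_multiplex, multidegree

WORDS = ["ball", "bat", "cat", "dog", "bone", "milk", "chair"]

assoc = [AssociationRecord("cat", "dog"), AssociationRecord("dog", "bone"),
         AssociationRecord("milk", "cat")]
feats = [FeatureRecord("cat", "has_fur"), FeatureRecord("dog", "has_fur"),
         FeatureRecord("ball", "is_round")]
cooc = [CooccurrenceRecord("ball", "dog", 60), CooccurrenceRecord("cat", "milk", 47),
        CooccurrenceRecord("cat", "dog", 30)]  # 30 <= 45: no edge
ipa = {"ball": ("b", "ɔ", "l"), "bat": ("b", "æ", "t"), "cat": ("k", "æ", "t"),
       "dog": ("d", "ɔ", "g")}

superset = Vocabulary(WORDS)
layers = [
    build_association_layer(assoc, superset),
    build_feature_layer(feats, superset),
    build_cooccurrence_layer(cooc, superset),
    build_phonological_layer(ipa, superset),
]
mln = intersect_vocabulary(WORDS, layers)

print(f"vocabulary after intersection: {list(mln.vocabulary.ids)}")
for layer in mln.layers:
    print(f"  {layer.name:13s} {layer.n_edges} edges: {sorted(layer.edges)}")
print(f"multiplex connected: {is_connected_multiplex(mln)}")
print("multidegrees:", {w: multidegree(mln, w) for w in mln.vocabulary.ids})
# 'chair' is dropped (isolated on every layer); 'bat' survives only through
# its phonological neighbourhood, showing how layers complement each other.
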