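"""Plain-text readers and writers.

Formats (all UTF-8, ``#`` lines are comments):

* multiplex edge list — one edge per line, ``layer<TAB>word1<TAB>word2``;
* vocabulary attribute CSV — word, frequency, length, ipa, pos;
* association TSV — cue, target[, strength];
* feature TSV — word, feature;
* co-occurrence TSV — word1, word2, count;
* phonological TSV — word, space-separated IPA tokens;
* CDI word-list TSV — one word per line;
* CDI norms CSV — word, month, fraction;
* trajectories CSV — label, position, word;
* gain-curve CSV — label, t, O, g, G, Z, p, method.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .aoa import AcquisitionTrajectory, CDINorms, TrajectoryEnsemble
from .build import AssociationRecord, CooccurrenceRecord, FeatureRecord, normalize_word
from .core import Layer, MultiplexNetwork, Vocabulary, Word
from .evaluate import GainCurve

__all__ = [
    "write_multiplex_edges",
    "read_multiplex_edges",
    "write_vocabulary_csv",
    "read_vocabulary_csv",
    "export_graphml",
    "read_association_tsv",
    "read_feature_tsv",
    "read_cooccurrence_tsv",
    "read_phonological_tsv",
    "read_cdi_list",
    "write_cdi_norms_csv",
    "read_cdi_norms_csv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_gain_curves_csv",
    "write_scores_csv",
]


def _data_lines(path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield line.split("\t")


def write_multiplex_edges(mln: MultiplexNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# layer\tword1\tword2\n")
        for layer in mln.layers:
            for u, v in sorted(layer.edges):
                fh.write(f"{layer.name}\t{u}\t{v}\n")


def read_multiplex_edges(path, vocabulary: Optional[Vocabulary] = None) -> MultiplexNetwork:
    """Read an extended edge list.  Without an explicit vocabulary, the node
    set is the union of all endpoints."""
    layers: dict[str, list] = {}
    for fields in _data_lines(path):
        if len(fields) != 3:
            raise ValueError(f"bad edge line {fields!r}: expected layer\\tword1\\tword2")
        name, u, v = fields
        layers.setdefault(name, []).append((u, v))
    if vocabulary is None:
        words = sorted({w for edges in layers.values() for e in edges for w in e})
        vocabulary = Vocabulary(words)
    return MultiplexNetwork(vocabulary, [Layer(n, e) for n, e in layers.items()])


def write_vocabulary_csv(vocab: Vocabulary, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["word", "frequency", "length", "ipa", "pos"])
        for word in vocab:
            w.writerow(
                [
                    word.id,
                    "" if word.frequency is None else word.frequency,
                    "" if word.length is None else word.length,
                    " ".join(word.ipa) if word.ipa else "",
                    word.pos_tag or "",
                ]
            )


def read_vocabulary_csv(path) -> Vocabulary:
    df = pd.read_csv(path, keep_default_na=False)
    words = []
    for _, row in df.iterrows():
        words.append(
            Word(
                str(row["word"]),
                frequency=float(row["frequency"]) if str(row.get("frequency", "")) != "" else None,
                length=int(row["length"]) if str(row.get("length", "")) != "" else None,
                ipa=tuple(str(row["ipa"]).split()) if str(row.get("ipa", "")) != "" else None,
                pos_tag=str(row["pos"]) or None if "pos" in row else None,
            )
        )
    return Vocabulary(words)


def export_graphml(mln: MultiplexNetwork, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for layer in mln.layers:
        p = out_dir / f"{layer.name}.graphml"
        nx.write_graphml(layer.to_networkx(mln.vocabulary), p)
        paths.append(p)
    return paths


def read_association_tsv(path) -> list[AssociationRecord]:
    out = []
    for f in _data_lines(path):
        cue, target = normalize_word(f[0]), normalize_word(f[1])
        strength = float(f[2]) if len(f) > 2 and f[2] else None
        if cue != target:
            out.append(AssociationRecord(cue, target, strength))
    return out


def read_feature_tsv(path) -> list[FeatureRecord]:
    return [
        FeatureRecord(normalize_word(f[0]), f[1].strip()) for f in _data_lines(path)
    ]


def read_cooccurrence_tsv(path) -> list[CooccurrenceRecord]:
    return [
        CooccurrenceRecord(normalize_word(f[0]), normalize_word(f[1]), int(f[2]))
        for f in _data_lines(path)
        if normalize_word(f[0]) != normalize_word(f[1])
    ]


def read_phonological_tsv(path) -> dict[str, tuple[str, ...]]:
    """Word -> IPA token sequence; the first transcription listed wins."""
    lex: dict[str, tuple[str, ...]] = {}
    for f in _data_lines(path):
        w = normalize_word(f[0])
        if w not in lex and len(f) > 1 and f[1].strip():
            lex[w] = tuple(f[1].split())
    return lex


def read_cdi_list(path) -> list[str]:
    return [normalize_word(f[0]) for f in _data_lines(path)]


def write_cdi_norms_csv(norms: CDINorms, path) -> None:
    rows = norms.production.stack()
    df = rows.rename_axis(["word", "month"]).reset_index(name="fraction")
    df.to_csv(path, index=False)


def read_cdi_norms_csv(path) -> CDINorms:
    df = pd.read_csv(path)
    table = df.pivot(index="word", columns="month", values="fraction")
    months = tuple(sorted(int(m) for m in table.columns))
    if table.isna().any().any():
        raise ValueError("norms table has missing word x month cells")
    return CDINorms(months, table)


def write_trajectories_csv(ensemble: TrajectoryEnsemble, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "position", "word"])
        for traj in ensemble:
            for pos, word in enumerate(traj.order, start=1):
                w.writerow([traj.label, pos, word])


def read_trajectories_csv(path) -> TrajectoryEnsemble:
    df = pd.read_csv(path)
    trajs = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("position")
        trajs.append(AcquisitionTrajectory(tuple(grp["word"]), label=str(label)))
    return TrajectoryEnsemble(trajs)


def write_gain_curves_csv(curves: Sequence[GainCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "label": c.label,
                    "t": c.t,
                    "O": c.O,
                    "g": c.g,
                    "G": c.G,
                    "Z": c.Z,
                    "p": c.pvalue if c.pvalue is not None else float("nan"),
                    "method": c.significance_method if c.significance_method else "",
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_scores_csv(tables, path) -> None:
    rows = []
    for tbl in tables:
        for w, s in sorted(tbl.scores.items()):
            rows.append({"word": w, "metric": tbl.metric_name, "scope": tbl.scope, "score": s})
    pd.DataFrame(rows).to_csv(path, index=False)
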