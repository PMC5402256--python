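"""Normative acquisition trajectories from CDI-style production norms, and
predicted trajectories from word scores.

CDI norms give, per word and month, the fraction of children reported to
produce the word.  A word counts as *known* once that fraction reaches 50%
in some month.  Normative orderings are sampled month by month: all words
that have crossed the threshold and are not yet placed form the candidate
pool, and are drawn sequentially without replacement with probability
proportional to the month's production fraction.  Words never reaching the
threshold are appended after the final month by the same rule using
final-month production.

Predicted trajectories rank words by descending score.  Tied scores are
handled either by emitting many random tie resolutions or, by default, by a
single canonical trajectory annotated with tie blocks so the evaluator can
compute exact expected overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .centrality import WordScoreTable
from .core import Vocabulary

__all__ = [
    "CDINorms",
    "AcquisitionTrajectory",
    "TrajectoryEnsemble",
    "sample_aoa_ordering",
    "sample_aoa_ensemble",
    "rank_by_score",
    "spawn_seeds",
]

DEFAULT_MONTHS = tuple(range(16, 31))
KNOWN_THRESHOLD = 0.5
_ZERO_FLOOR = 1e-6


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


@dataclass
class CDINorms:
    """Word x month table of production fractions."""

    months: tuple[int, ...]
    production: pd.DataFrame  # index: word id, columns: months, values in [0, 1]

    def __post_init__(self) -> None:
        self.months = tuple(int(m) for m in self.months)
        self.production = self.production[list(self.months)]
        vals = self.production.to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("production fractions must be in [0, 1]")

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.production.index)

    def check_covers(self, vocab: Vocabulary) -> None:
        missing = [w for w in vocab.ids if w not in self.production.index]
        if missing:
            raise ValueError(f"norms missing words: {missing[:10]}")

    def first_crossing_month(self, threshold: float = KNOWN_THRESHOLD) -> pd.Series:
        """First month each word's production reaches the threshold (NaN if never)."""
        vals = self.production.to_numpy() >= threshold
        months = np.asarray(self.months, dtype=float)
        out = np.full(len(self.production), np.nan)
        for i in range(len(self.production)):
            hits = np.nonzero(vals[i])[0]
            if hits.size:
                out[i] = months[hits[0]]
        return pd.Series(out, index=self.production.index, name="first_crossing")

    def inventory_size_by_month(self, threshold: float = KNOWN_THRESHOLD) -> dict[int, int]:
        """Month -> number of words known by that month (production has reached
        the threshold at that month or earlier)."""
        crossing = self.first_crossing_month(threshold)
        return {m: int((crossing <= m).sum()) for m in self.months}


@dataclass
class AcquisitionTrajectory:
    """A permutation of the vocabulary: the order in which words are learned.

    ``tie_blocks`` (optional) lists 0-based [start, end) position ranges
    within which the order is arbitrary (tied word scores); evaluators may
    average over resolutions of these blocks exactly.
    """

    order: tuple[str, ...]
    label: str = ""
    tie_blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("trajectory is not a permutation (duplicate words)")
        self.order = tuple(self.order)

    def __len__(self) -> int:
        return len(self.order)

    def positions(self) -> dict[str, int]:
        """Word -> 1-based position."""
        return {w: i + 1 for i, w in enumerate(self.order)}


@dataclass
class TrajectoryEnsemble:
    trajectories: list[AcquisitionTrajectory]
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("empty trajectory ensemble")
        ref = set(self.trajectories[0].order)
        for t in self.trajectories[1:]:
            if set(t.order) != ref:
                raise ValueError("ensemble trajectories cover different vocabularies")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


def _weighted_sequential_order(
    words: Sequence[str], weights: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Order by successive sampling proportional to weight, without
    replacement (Efraimidis-Spirakis exponential-race keys)."""
    if len(words) == 0:
        return []
    w = np.maximum(np.asarray(weights, dtype=float), _ZERO_FLOOR)
    keys = rng.exponential(size=len(w)) / w
    return [words[i] for i in np.argsort(keys, kind="stable")]


def sample_aoa_ordering(
    norms: CDINorms,
    threshold: float = KNOWN_THRESHOLD,
    seed: int = 0,
    label: str = "aoa",
) -> AcquisitionTrajectory:
    """Sample one normative acquisition ordering from CDI norms.

    Month by month, words whose production has reached ``threshold`` (now or
    at any earlier month) and are not yet placed are appended in an order
    drawn sequentially with probability proportional to the current month's
    production fraction.  Words still below threshold after the final month
    are appended by the same rule using final-month production (fractions of
    zero get a 1e-6 floor).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rng = np.random.default_rng(seed)
    prod = norms.production
    words = np.array(prod.index)
    vals = prod.to_numpy()
    placed = np.zeros(len(words), dtype=bool)
    eligible = np.zeros(len(words), dtype=bool)
    order: list[str] = []
    for mi, _month in enumerate(norms.months):
        eligible |= vals[:, mi] >= threshold
        pool = np.nonzero(eligible & ~placed)[0]
        if pool.size == 0:
            continue
        chunk = _weighted_sequential_order(list(words[pool]), vals[pool, mi], rng)
        order.extend(chunk)
        placed[pool] = True
    rest = np.nonzero(~placed)[0]
    if rest.size:
        order.extend(_weighted_sequential_order(list(words[rest]), vals[rest, -1], rng))
    return AcquisitionTrajectory(tuple(order), label=label)


def sample_aoa_ensemble(
    norms: CDINorms,
    n: int = 30,
    seed: int = 0,
    threshold: float = KNOWN_THRESHOLD,
) -> TrajectoryEnsemble:
    """Ensemble of ``n`` independent normative orderings, reproducible from
    the master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = spawn_seeds(seed, n)
    trajs = [
        sample_aoa_ordering(norms, threshold=threshold, seed=s, label=f"aoa_sample_{i}")
        for i, s in enumerate(seeds)
    ]
    return TrajectoryEnsemble(trajs, seeds)


def rank_by_score(
    scores: WordScoreTable,
    tie_policy: str = "expected",
    n_resolutions: int = 100,
    seed: int = 0,
    label: Optional[str] = None,
) -> TrajectoryEnsemble:
    """Predicted trajectory: words in descending score order.

    ``tie_policy="expected"`` returns one canonical trajectory (ties broken
    by word id) annotated with tie blocks, from which evaluators compute
    exact expected overlaps; ``"resolutions"`` returns ``n_resolutions``
    trajectories with every tied block independently shuffled.
    """
    label = label or f"{scores.scope}:{scores.metric_name}"
    items = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    order = [w for w, _ in items]
    vals = [s for _, s in items]
    blocks: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(vals) + 1):
        if i == len(vals) or vals[i] != vals[start]:
            if i - start > 1:
                blocks.append((start, i))
            start = i
    if tie_policy == "expected":
        traj = AcquisitionTrajectory(tuple(order), label=label, tie_blocks=tuple(blocks))
        return TrajectoryEnsemble([traj])
    if tie_policy == "resolutions":
        if n_resolutions < 1:
            raise ValueError("n_resolutions must be >= 1")
        rng = np.random.default_rng(seed)
        trajs = []
        for r in range(n_resolutions):
            arr = list(order)
            for a, b in blocks:
                perm = rng.permutation(b - a)
                arr[a:b] = [order[a + p] for p in perm]
            trajs.append(AcquisitionTrajectory(tuple(arr), label=f"{label}#res{r}"))
        return TrajectoryEnsemble(trajs)
    raise ValueError(f"unknown tie_policy {tie_policy!r}")
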