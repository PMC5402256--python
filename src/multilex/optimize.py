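"""Optimal convex combinations of per-layer word scores.

A combined word score is s_w = Σ_l α_l · ŝ_l(w) with nonnegative layer
influences α summing to one and ŝ_l the per-layer scores brought to a
common scale (min-max by default).  The influences are fitted by
differential evolution to maximize the mean vocabulary-normalized word gain
of the resulting ordering over a window of inventory sizes.  Robustness
follows a Monte Carlo hold-out scheme: each run removes a random 20% of the
words from the ordering construction, and fitted influences are averaged
over runs; final performance is evaluated on the full vocabulary.  A control
re-runs the whole procedure on a degree-preserving randomization of every
layer, which destroys the correlated multiplex structure while keeping
degree sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .aoa import TrajectoryEnsemble, spawn_seeds
from .centrality import WordScoreTable, layer_centrality
from .core import MultiplexNetwork
from .evaluate import GainCurve, RandomBaseline, _expected_curve, gain_curve, random_baseline
from .topology import _randomize

logger = logging.getLogger(__name__)

__all__ = [
    "LayerWeights",
    "DEParams",
    "OptimizationConfig",
    "OptimizationResult",
    "combined_score",
    "objective",
    "optimize_weights",
    "randomized_multiplex_control",
]

SIMPLEX_TOL = 1e-9


@dataclass
class LayerWeights:
    """Convex layer influences: nonnegative, summing to one."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < -SIMPLEX_TOL):
            raise ValueError(f"negative layer weight in {self.weights}")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"layer weights must sum to 1, got {vals.sum()}")
        self.weights = {k: max(0.0, float(v)) for k, v in self.weights.items()}

    @classmethod
    def from_raw(cls, names: Sequence[str], raw: Sequence[float]) -> "LayerWeights":
        v = np.maximum(np.asarray(raw, dtype=float), 0.0)
        s = v.sum()
        if s <= 0:
            raise ValueError("all-zero weight vector")
        return cls(dict(zip(names, v / s)))

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[n] for n in names])


def _normalize_columns(mat: np.ndarray, scheme: str) -> np.ndarray:
    """Bring each column (one layer's scores) to a common scale."""
    out = np.empty_like(mat, dtype=float)
    for j in range(mat.shape[1]):
        col = mat[:, j].astype(float)
        if scheme == "minmax":
            lo, hi = col.min(), col.max()
            out[:, j] = (col - lo) / (hi - lo) if hi > lo else 0.0
        elif scheme == "rank":
            # average ranks for ties, scaled to [0, 1]
            order = np.argsort(col, kind="stable")
            ranks = np.empty(len(col))
            sorted_col = col[order]
            i = 0
            while i < len(col):
                j2 = i
                while j2 + 1 < len(col) and sorted_col[j2 + 1] == sorted_col[i]:
                    j2 += 1
                ranks[order[i : j2 + 1]] = 0.5 * (i + j2)
                i = j2 + 1
            out[:, j] = ranks / max(len(col) - 1, 1)
        elif scheme == "zscore":
            sd = col.std()
            out[:, j] = (col - col.mean()) / sd if sd > 0 else 0.0
        else:
            raise ValueError(f"unknown normalization {scheme!r}")
    return out


def combined_score(
    per_layer_scores: Mapping[str, WordScoreTable],
    weights: LayerWeights,
    normalization: str = "minmax",
) -> WordScoreTable:
    """Convex combination of normalized per-layer scores."""
    unknown = set(weights.weights) - set(per_layer_scores)
    if unknown:
        raise ValueError(f"weights reference unknown layers: {sorted(unknown)}")
    names = list(weights.weights)
    words = sorted(per_layer_scores[names[0]].scores)
    for n in names[1:]:
        if sorted(per_layer_scores[n].scores) != words:
            raise ValueError("per-layer score tables cover different vocabularies")
    mat = np.array([[per_layer_scores[n].scores[w] for n in names] for w in words])
    norm = _normalize_columns(mat, normalization)
    s = norm @ weights.as_array(names)
    metric = per_layer_scores[names[0]].metric_name
    return WordScoreTable(f"combined_{metric}", "multiplex", dict(zip(words, map(float, s))))


class _ObjectiveContext:
    """Precomputed structures for fast repeated objective evaluations.

    Holds the normalized score matrix over retained (non-held-out) words,
    reference position arrays restricted to the retained words, the analytic
    baseline for the reduced vocabulary, and the evaluation window (scaled
    proportionally when words are held out).
    """

    def __init__(
        self,
        per_layer_scores: Mapping[str, WordScoreTable],
        layer_names: Sequence[str],
        refs: TrajectoryEnsemble,
        window: Optional[tuple[int, int]] = None,
        holdout: frozenset = frozenset(),
        normalization: str = "minmax",
    ):
        full_vocab = list(refs.trajectories[0].order)
        n_full = len(full_vocab)
        retained = [w for w in sorted(full_vocab) if w not in holdout]
        self.words = retained
        n = len(retained)
        if n < 2:
            raise ValueError("fewer than 2 words retained")
        idx = {w: i for i, w in enumerate(retained)}
        mat = np.array(
            [[per_layer_scores[l].scores[w] for l in layer_names] for w in retained]
        )
        self.S = _normalize_columns(mat, normalization)
        self.layer_names = list(layer_names)
        self.ref_pos = []
        for r in refs:
            pos = np.empty(n, dtype=np.int64)
            p = 1
            for w in r.order:
                if w in idx:
                    pos[idx[w]] = p
                    p += 1
            self.ref_pos.append(pos)
        base = random_baseline(n)
        self.base_mean = base.mean
        self.N = n
        if window is None:
            lo, hi = 1, n
        else:
            lo, hi = window
            if lo > hi:
                raise ValueError("empty window")
            scale = n / n_full
            lo = max(1, int(round(lo * scale)))
            hi = min(n, max(lo, int(round(hi * scale))))
        self.window = (lo, hi)
        self._tvals = np.arange(1, n + 1, dtype=float)

    def mean_G(self, raw_weights: np.ndarray) -> float:
        w = np.maximum(np.asarray(raw_weights, dtype=float), 0.0)
        s = w.sum()
        if s <= 0:
            return -np.inf
        scores = self.S @ (w / s)
        order = np.argsort(-scores, kind="stable")
        sv = scores[order]
        # tie blocks: runs of equal combined scores
        blocks = []
        a = 0
        for i in range(1, self.N + 1):
            if i == self.N or sv[i] != sv[a]:
                if i - a > 1:
                    blocks.append((a, i))
                a = i
        curves = [_expected_curve(pos[order], blocks) for pos in self.ref_pos]
        O = np.mean(curves, axis=0)
        G = (O - self.base_mean) / self._tvals
        lo, hi = self.window
        return float(G[lo - 1 : hi].mean())


def objective(
    weights: LayerWeights,
    per_layer_scores: Mapping[str, WordScoreTable],
    ref_ensemble: TrajectoryEnsemble,
    baseline: Optional[RandomBaseline] = None,
    window: Optional[tuple[int, int]] = None,
    holdout_mask: frozenset = frozenset(),
    normalization: str = "minmax",
) -> float:
    """Mean normalized word gain of the combined-score ordering.

    Held-out words are removed from the ordering construction and from the
    reference orderings; the analytic baseline is recomputed for the reduced
    vocabulary (``baseline`` may override it when no words are held out).
    """
    names = list(weights.weights)
    ctx = _ObjectiveContext(
        per_layer_scores, names, ref_ensemble, window, holdout_mask, normalization
    )
    if baseline is not None and not holdout_mask:
        ctx.base_mean = baseline.mean
    return ctx.mean_G(weights.as_array(names))


@dataclass
class DEParams:
    """Differential-evolution settings (scipy semantics)."""

    popsize: int = 15
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    maxiter: int = 200
    tol: float = 1e-6
    init: str = "latinhypercube"


@dataclass
class OptimizationConfig:
    metric: str = "degree"  # degree | closeness | betweenness | clustering
    objective_window: Optional[tuple[int, int]] = None
    holdout_fraction: float = 0.2
    n_holdout_configs: int = 50
    n_aoa_orderings: int = 30
    holdout_mode: str = "induced"  # induced | masked
    normalization: str = "minmax"
    drop_layers: tuple[str, ...] = ()
    de: DEParams = field(default_factory=DEParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.n_holdout_configs < 1 or self.n_aoa_orderings < 1:
            raise ValueError("ensemble counts must be >= 1")


@dataclass
class OptimizationResult:
    mean_weights: LayerWeights
    sd_weights: dict[str, float]
    per_run_weights: list[dict[str, float]]
    per_run_objective: list[float]
    achieved_curve: GainCurve
    mean_objective: float
    converged: list[bool]
    config: OptimizationConfig


def _per_layer_scores(mln: MultiplexNetwork, metric: str, layer_names) -> dict[str, WordScoreTable]:
    return {
        name: layer_centrality(mln.layer(name), metric, mln.vocabulary)
        for name in layer_names
    }


def optimize_weights(
    config: OptimizationConfig,
    mln: MultiplexNetwork,
    ref_ensemble: TrajectoryEnsemble,
) -> OptimizationResult:
    """Fit layer influences by differential evolution with hold-out averaging.

    For each hold-out configuration a random ``holdout_fraction`` of the
    words is removed; in ``induced`` mode the per-layer scores are recomputed
    on the induced sub-multiplex, in ``masked`` mode the full-network scores
    are merely restricted.  The simplex is parameterized by L box-bounded
    nonnegative coordinates normalized by their sum inside the objective.
    The returned achieved curve evaluates the mean fitted weights on all
    words of the full network.
    """
    layer_names = [n for n in mln.layer_names if n not in config.drop_layers]
    L = len(layer_names)
    if L < 2:
        raise ValueError("need at least 2 layers to optimize over")
    vocab_ids = list(mln.vocabulary.ids)
    n = len(vocab_ids)
    n_hold = int(round(config.holdout_fraction * n))
    seeds = spawn_seeds(config.seed, 2 * config.n_holdout_configs)
    full_scores = _per_layer_scores(mln, config.metric, layer_names)

    per_run_w, per_run_obj, converged = [], [], []
    for i in range(config.n_holdout_configs):
        rng = np.random.default_rng(seeds[2 * i])
        holdout = frozenset(rng.choice(vocab_ids, size=n_hold, replace=False)) if n_hold else frozenset()
        if config.holdout_mode == "induced" and holdout:
            sub = mln.induced(set(vocab_ids) - holdout)
            scores = _per_layer_scores(sub, config.metric, layer_names)
        elif config.holdout_mode in ("induced", "masked"):
            scores = full_scores
        else:
            raise ValueError(f"unknown holdout_mode {config.holdout_mode!r}")
        ctx = _ObjectiveContext(
            scores, layer_names, ref_ensemble, config.objective_window, holdout,
            config.normalization,
        )
        res = differential_evolution(
            lambda x: -ctx.mean_G(x),
            bounds=[(0.0, 1.0)] * L,
            popsize=config.de.popsize,
            mutation=config.de.mutation,
            recombination=config.de.recombination,
            maxiter=config.de.maxiter,
            tol=config.de.tol,
            init=config.de.init,
            seed=seeds[2 * i + 1],
            polish=False,
        )
        if not res.success:
            logger.warning("DE run %d did not converge: %s", i, res.message)
        w = LayerWeights.from_raw(layer_names, res.x)
        per_run_w.append(dict(w.weights))
        per_run_obj.append(-float(res.fun))
        converged.append(bool(res.success))

    mean_raw = np.mean([[w[l] for l in layer_names] for w in per_run_w], axis=0)
    sd_raw = np.std([[w[l] for l in layer_names] for w in per_run_w], axis=0)
    mean_w = LayerWeights.from_raw(layer_names, mean_raw)

    # performance of the averaged influences, evaluated on all words
    from .aoa import rank_by_score

    final = combined_score(full_scores, mean_w, config.normalization)
    pred = rank_by_score(final, tie_policy="expected", label=f"optimal_{config.metric}")
    curve = gain_curve(pred, ref_ensemble, random_baseline(n))
    return OptimizationResult(
        mean_weights=mean_w,
        sd_weights=dict(zip(layer_names, map(float, sd_raw))),
        per_run_weights=per_run_w,
        per_run_objective=per_run_obj,
        achieved_curve=curve,
        mean_objective=float(np.mean(per_run_obj)),
        converged=converged,
        config=config,
    )


def randomized_multiplex_control(
    config: OptimizationConfig,
    mln: MultiplexNetwork,
    ref_ensemble: TrajectoryEnsemble,
    n_swaps_per_edge: int = 10,
) -> OptimizationResult:
    """Re-run the optimization on a degree-preserving randomization of every
    layer.  Gains achievable on the randomized multiplex quantify how much of
    the empirical predictability rests on the actual correlated topology."""
    rng = np.random.default_rng(spawn_seeds(config.seed, 1)[0])
    rand_layers = [_randomize(l, n_swaps_per_edge, rng) for l in mln.layers]
    control = MultiplexNetwork(mln.vocabulary, rand_layers)
    return optimize_weights(config, control, ref_ensemble)
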