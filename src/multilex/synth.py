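"""Synthetic multiplex lexicons with planted acquisition structure.

The generator emulates the statistical shape of the empirical data the
pipeline is designed for, so every stage can run end to end without any
download:

* four undirected layers on a shared vocabulary whose degree distributions
  are exponential-like (feature-sharing, phonological) or heavy-tailed
  (association, co-occurrence), with tunable cross-layer degree correlation
  (latent-Gaussian copula), pairwise edge-overlap boosts and triadic-closure
  clustering;
* Zipfian word frequencies and word lengths anti-correlated with frequency;
* CDI-like production norms over months 16-30 in which acquisition onset is
  a monotone function of a *planted* convex combination of per-layer word
  scores plus Gaussian noise — the ground truth that weight optimization is
  later asked to recover.

Default scales follow the empirical study conditions: N = 529 words, layer
mean degrees 9.3 / 9.0 / 8.1 / 1.31.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm as _gaussian

from .aoa import CDINorms, spawn_seeds
from .centrality import layer_centrality
from .core import Layer, MultiplexNetwork, Vocabulary, Word
from .optimize import LayerWeights, combined_score

__all__ = [
    "DegreeModel",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_multiplex",
    "generate_attributes",
    "apply_attributes",
    "generate_cdi_norms",
    "generate_dataset",
]

DEFAULT_LAYER_NAMES = ("association", "feature", "cooccurrence", "phonological")


@dataclass(frozen=True)
class DegreeModel:
    """Marginal degree distribution of one layer.

    ``kind``: "exponential" (mean) or "powerlaw" (Pareto with ``exponent`` >
    2 so the mean exists; samples capped at N-1).
    """

    kind: str
    mean: float
    exponent: float = 2.5

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean degree must be > 0")
        if self.kind == "powerlaw" and self.exponent <= 2:
            raise ValueError("powerlaw exponent must be > 2 for a finite target mean")
        if self.kind not in ("exponential", "powerlaw"):
            raise ValueError(f"unknown degree model {self.kind!r}")

    def quantile(self, u: np.ndarray, cap: Optional[float] = None) -> np.ndarray:
        """Inverse CDF of the continuous marginal, truncated at ``cap``.

        For the power law (pdf ∝ k^-exponent, Pareto shape exponent-1) the
        scale is adjusted so the mean of the *capped* variable hits the
        target, compensating the truncated heavy tail.
        """
        u = np.clip(u, 1e-12, 1 - 1e-12)
        if self.kind == "exponential":
            vals = -self.mean * np.log1p(-u)
        else:
            alpha = self.exponent - 1
            k_min = self.mean * (alpha - 1) / alpha
            if cap is not None and cap > k_min:
                from scipy.optimize import brentq

                def capped_mean(k):
                    return k * alpha / (alpha - 1) - k**alpha * cap ** (1 - alpha) / (alpha - 1)

                if capped_mean(k_min) < self.mean - 1e-12:
                    hi = min(cap, self.mean * 4)
                    if capped_mean(hi) > self.mean:
                        k_min = brentq(lambda k: capped_mean(k) - self.mean, k_min, hi)
            vals = k_min * (1 - u) ** (-1.0 / alpha)
        return np.minimum(vals, cap) if cap is not None else vals


def _default_degree_models() -> tuple[DegreeModel, ...]:
    return (
        DegreeModel("powerlaw", 9.3),
        DegreeModel("exponential", 9.0),
        DegreeModel("powerlaw", 8.1),
        DegreeModel("exponential", 1.31),
    )


def _default_correlation() -> np.ndarray:
    # Kendall-tau targets: feature/co-occurrence negative, co-occurrence/
    # phonological positive, other pairs uncorrelated
    m = np.eye(4)
    m[1, 2] = m[2, 1] = -0.16
    m[2, 3] = m[3, 2] = 0.27
    return m


def _default_overlap() -> np.ndarray:
    # modest edge sharing among the three semantic layers only
    m = np.zeros((4, 4))
    for i, j in ((0, 1), (0, 2), (1, 2)):
        m[i, j] = m[j, i] = 0.05
    return m


@dataclass
class SyntheticSpec:
    N: int = 529
    layer_names: tuple[str, ...] = DEFAULT_LAYER_NAMES
    degree_models: tuple[DegreeModel, ...] = field(default_factory=_default_degree_models)
    degree_correlation: np.ndarray = field(default_factory=_default_correlation)
    overlap_boost: np.ndarray = field(default_factory=_default_overlap)
    clustering_boost: tuple[float, ...] = (0.1, 0.3, 0.3, 0.1)
    planted_weights: Optional[LayerWeights] = None
    planted_metric: str = "degree"
    aoa_noise_sd: float = 0.5
    months: tuple[int, ...] = tuple(range(16, 31))
    logistic_slope: float = 2.0
    zipf_exponent: float = 1.0
    length_range: tuple[int, int] = (2, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.layer_names)
        if len(self.degree_models) != L or len(self.clustering_boost) != L:
            raise ValueError("per-layer settings must match the number of layers")
        self.degree_correlation = np.asarray(self.degree_correlation, dtype=float)
        self.overlap_boost = np.asarray(self.overlap_boost, dtype=float)
        for m in (self.degree_correlation, self.overlap_boost):
            if m.shape != (L, L) or not np.allclose(m, m.T):
                raise ValueError("correlation/overlap matrices must be symmetric LxL")
        if self.aoa_noise_sd < 0 or self.logistic_slope <= 0:
            raise ValueError("aoa_noise_sd must be >= 0 and logistic_slope > 0")
        if self.planted_weights is None:
            w = [0.5, 0.25, 0.2, 0.05][: len(self.layer_names)]
            self.planted_weights = LayerWeights.from_raw(self.layer_names, w)


def _nearest_correlation(m: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to make a symmetric matrix positive semidefinite."""
    vals, vecs = np.linalg.eigh(m)
    vals = np.maximum(vals, 1e-10)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _graphical(seq: np.ndarray, n: int) -> list[int]:
    seq = np.minimum(np.maximum(seq, 0), n - 1).astype(int)
    if seq.sum() % 2:
        seq[int(np.argmax(seq))] += 1 if seq.max() < n - 1 else -1
    while not nx.is_graphical(list(seq)):
        seq[int(np.argmax(seq))] -= 1
        if seq.sum() % 2:
            seq[int(np.argmin(seq))] += 1
    return [int(k) for k in seq]


def generate_multiplex(spec: SyntheticSpec) -> MultiplexNetwork:
    """Sample a multiplex with copula-coupled degrees, per-layer marginals,
    triadic-closure clustering and injected edge overlap."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.N, len(spec.layer_names)
    words = [f"w{i:04d}" for i in range(n)]
    # latent Gaussian copula: Pearson r targeting the requested Kendall tau
    pearson = _nearest_correlation(np.sin(np.pi * spec.degree_correlation / 2.0))
    chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(L))
    z = rng.standard_normal((n, L)) @ chol.T
    u = _gaussian.cdf(z)

    layers = []
    for j, (name, model) in enumerate(zip(spec.layer_names, spec.degree_models)):
        raw = model.quantile(u[:, j], cap=n - 1)
        frac = raw - np.floor(raw)  # stochastic rounding keeps the mean
        deg = _graphical(np.floor(raw) + (rng.random(n) < frac), n)
        g = nx.havel_hakimi_graph(deg)
        # havel_hakimi does not guarantee node i gets deg[i]; rank-match the
        # realized degrees back onto the copula-coupled target sequence
        realized = np.array([g.degree(i) for i in range(n)])
        if not np.array_equal(realized, np.asarray(deg)):
            src = np.argsort(-realized, kind="stable")
            dst = np.argsort(-np.asarray(deg), kind="stable")
            g = nx.relabel_nodes(g, {int(s): int(d) for s, d in zip(src, dst)}, copy=True)
        m = g.number_of_edges()
        if m >= 2:
            try:
                nx.double_edge_swap(
                    g, nswap=10 * m, max_tries=1000 * m, seed=int(rng.integers(2**31 - 1))
                )
            except nx.NetworkXError:
                pass
        # triadic closure: close random open wedges to boost clustering
        target_extra = int(spec.clustering_boost[j] * m)
        nodes = [v for v in g if g.degree(v) >= 2]
        added = 0
        attempts = 0
        while added < target_extra and attempts < 20 * max(target_extra, 1) and nodes:
            v = nodes[int(rng.integers(len(nodes)))]
            nbrs = list(g[v])
            a, b = rng.choice(len(nbrs), size=2, replace=False)
            if not g.has_edge(nbrs[a], nbrs[b]):
                g.add_edge(nbrs[a], nbrs[b])
                added += 1
            attempts += 1
        layers.append(Layer(name, ((words[a], words[b]) for a, b in g.edges())))

    # overlap injection: copy a fraction of each layer's edges into the other
    for i in range(L):
        for j in range(i + 1, L):
            boost = spec.overlap_boost[i, j]
            if boost <= 0:
                continue
            for src, dst in ((layers[i], layers[j]), (layers[j], layers[i])):
                edges = sorted(src.edges)
                k = int(round(boost * len(edges)))
                if k == 0 or not edges:
                    continue
                for idx in rng.choice(len(edges), size=min(k, len(edges)), replace=False):
                    dst.add_edge(*edges[idx])
    return MultiplexNetwork(Vocabulary(words), layers)


def generate_attributes(
    vocab: Vocabulary,
    zipf_exponent: float = 1.0,
    length_range: tuple[int, int] = (2, 10),
    seed: int = 0,
) -> pd.DataFrame:
    """Zipfian frequencies and lengths anti-correlated with frequency."""
    if zipf_exponent <= 0:
        raise ValueError("zipf_exponent must be > 0")
    rng = np.random.default_rng(seed)
    n = len(vocab)
    ranks = rng.permutation(n) + 1  # frequency rank of each word, 1 = most frequent
    freq = 1000.0 * ranks.astype(float) ** (-zipf_exponent)
    lo, hi = length_range
    base = lo + (hi - lo) * (ranks - 1) / max(n - 1, 1)  # rarer words are longer
    length = np.clip(np.round(base + rng.normal(0, 1.0, size=n)), lo, hi).astype(int)
    return pd.DataFrame({"word": list(vocab.ids), "frequency": freq, "length": length})


def apply_attributes(vocab: Vocabulary, attrs: pd.DataFrame) -> None:
    """Write frequency/length columns onto the Word objects in place."""
    table = attrs.set_index("word")
    for w in vocab:
        if w.id in table.index:
            w.frequency = float(table.loc[w.id, "frequency"])
            w.length = int(table.loc[w.id, "length"])


def generate_cdi_norms(
    mln: MultiplexNetwork,
    planted_weights: LayerWeights,
    planted_metric: str = "degree",
    aoa_noise_sd: float = 0.0,
    months: Sequence[int] = tuple(range(16, 31)),
    logistic_slope: float = 2.0,
    seed: int = 0,
) -> tuple[CDINorms, dict]:
    """CDI-like production norms driven by a planted combined word score.

    The combined score (convex combination of per-layer ``planted_metric``
    scores) is mapped monotonically decreasing to an acquisition-onset month
    m_w, jittered with Gaussian noise of sd ``aoa_noise_sd`` months; the
    production curve is the logistic p_w(m) = 1/(1+exp(-slope (m - m_w))).
    Onsets are confined so every word's final-month production is >= 0.95
    (hence every word crosses 50% within the month range).
    """
    months = tuple(int(m) for m in months)
    rng = np.random.default_rng(seed)
    per_layer = {
        name: layer_centrality(mln.layer(name), planted_metric, mln.vocabulary)
        for name in planted_weights.weights
    }
    planted = combined_score(per_layer, planted_weights, "minmax")
    words = list(mln.vocabulary.ids)
    s = np.array([planted.scores[w] for w in words])
    rng_span = s.max() - s.min()
    s_norm = (s - s.min()) / rng_span if rng_span > 0 else np.zeros_like(s)
    m_lo, m_hi = months[0], months[-1]
    delta = np.log(19.0) / logistic_slope  # logistic(slope*delta) = 0.95
    onset_hi = m_hi - delta
    onset = m_lo + (1.0 - s_norm) * (onset_hi - m_lo)
    if aoa_noise_sd > 0:
        onset = onset + rng.normal(0.0, aoa_noise_sd, size=len(words))
    onset = np.clip(onset, m_lo, onset_hi)
    grid = np.asarray(months, dtype=float)
    prod = 1.0 / (1.0 + np.exp(-logistic_slope * (grid[None, :] - onset[:, None])))
    norms = CDINorms(months, pd.DataFrame(prod, index=words, columns=list(months)))
    truth = {
        "planted_weights": dict(planted_weights.weights),
        "planted_metric": planted_metric,
        "planted_scores": dict(zip(words, map(float, s))),
        "onset_months": dict(zip(words, map(float, onset))),
    }
    return norms, truth


@dataclass
class SyntheticDataset:
    mln: MultiplexNetwork
    norms: CDINorms
    attributes: pd.DataFrame
    ground_truth: dict
    spec: SyntheticSpec


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full synthetic study: multiplex, attributes and planted CDI norms."""
    s_mlx, s_attr, s_norms = spawn_seeds(spec.seed, 3)
    mln = generate_multiplex(SyntheticSpec(**{**spec.__dict__, "seed": s_mlx}))
    attrs = generate_attributes(mln.vocabulary, spec.zipf_exponent, spec.length_range, s_attr)
    apply_attributes(mln.vocabulary, attrs)
    norms, truth = generate_cdi_norms(
        mln,
        spec.planted_weights,
        spec.planted_metric,
        spec.aoa_noise_sd,
        spec.months,
        spec.logistic_slope,
        s_norms,
    )
    return SyntheticDataset(mln, norms, attrs, truth, spec)
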