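"""Overlap, word gain, normalized gain, Z-scores and significance.

A predicted trajectory τ is scored against an ensemble of normative
age-of-acquisition orderings by the overlap O(τ, t): how many of the first
t predicted words are among the first t normatively learned words, averaged
over the ensemble.  The word gain subtracts the expectation for a uniformly
random ordering,

    g(τ, t) = O(τ, t) - E[O(τ_ran, t)],      E[O(τ_ran, t)] = t²/N,

the vocabulary-normalized gain is G = g/t, and the Z-score divides g by the
standard deviation of the random overlap (hypergeometric: the first t words
of a random permutation form a uniform t-subset, so the overlap with any
fixed t-set is Hypergeometric(N, t, t)).

Significance: the random-overlap distribution is near-Gaussian once enough
words are acquired, so for t above a cutoff (default 60) a one-sided
Gaussian p-value is attached to Z; below the cutoff, direct sampling of
random orderings is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .aoa import AcquisitionTrajectory, TrajectoryEnsemble

__all__ = [
    "RandomBaseline",
    "GainCurve",
    "StageWindows",
    "critical_z",
    "overlap",
    "expected_overlap_curve",
    "mean_overlap_curve",
    "mean_overlap",
    "random_baseline",
    "gain_curve",
    "significance",
    "stage_report",
]

GAUSSIAN_MIN_T = 60
DEFAULT_ALPHA = 0.025
DEFAULT_N_DIRECT = 100_000

Prediction = Union[AcquisitionTrajectory, TrajectoryEnsemble]


def critical_z(alpha: float = DEFAULT_ALPHA) -> float:
    """One-sided Gaussian critical value; 1.96 at the 2.5% level."""
    return float(norm.isf(alpha))


def overlap(tau: AcquisitionTrajectory, ref: AcquisitionTrajectory, t: int) -> int:
    """|{first t words of tau} ∩ {first t words of ref}| (ties ignored)."""
    n = len(tau)
    if len(ref) != n or set(tau.order) != set(ref.order):
        raise ValueError("trajectories must cover the same vocabulary")
    if not 1 <= t <= n:
        raise ValueError(f"t must be in [1, {n}], got {t}")
    return len(set(tau.order[:t]) & set(ref.order[:t]))


def expected_overlap_curve(tau: AcquisitionTrajectory, ref: AcquisitionTrajectory) -> np.ndarray:
    """O(τ, t) for every t = 1..N, with exact expectations over tie blocks.

    Within a tie block occupying (1-based) positions a+1..b, the first t-a
    of its m words are an exchangeable uniform subset, so the block's
    contribution at a ≤ t < b is (t-a)/m times the number of its words the
    reference has placed by t.
    """
    n = len(tau)
    pos_ref = np.empty(n, dtype=np.int64)
    ref_pos_of = {w: i + 1 for i, w in enumerate(ref.order)}
    for i, w in enumerate(tau.order):
        pos_ref[i] = ref_pos_of[w]
    return _expected_curve(pos_ref, tau.tie_blocks)


def _expected_curve(pos_ref: np.ndarray, tie_blocks) -> np.ndarray:
    """Array core of :func:`expected_overlap_curve`: ``pos_ref[i]`` is the
    1-based reference position of the word at prediction position i+1."""
    n = len(pos_ref)
    end = np.arange(1, n + 1)  # 1-based position of each word's block end
    for a, b in tie_blocks:
        end[a:b] = b
    m = np.maximum(end, pos_ref)
    curve = np.cumsum(np.bincount(m, minlength=n + 1)[1:]).astype(float)
    for a, b in tie_blocks:
        size = b - a
        if size < 2:
            continue
        sr = np.sort(pos_ref[a:b])
        ts = np.arange(a + 1, b)  # 1-based t values strictly inside the block
        c = np.searchsorted(sr, ts, side="right")
        curve[ts - 1] += (ts - a) / size * c
    return curve


def mean_overlap_curve(pred: Prediction, refs: TrajectoryEnsemble) -> np.ndarray:
    """Mean of O(τ, t) over prediction members and reference ensemble."""
    preds = pred.trajectories if isinstance(pred, TrajectoryEnsemble) else [pred]
    curves = [expected_overlap_curve(p, r) for p in preds for r in refs]
    return np.mean(curves, axis=0)


def mean_overlap(pred: Prediction, refs: TrajectoryEnsemble, t: int) -> float:
    """Mean overlap at a single inventory size t."""
    curve = mean_overlap_curve(pred, refs)
    if not 1 <= t <= len(curve):
        raise ValueError(f"t must be in [1, {len(curve)}]")
    return float(curve[t - 1])


@dataclass
class RandomBaseline:
    """Mean and sd of the overlap of a uniformly random ordering, per t."""

    N: int
    mean: np.ndarray  # index t-1
    sd: np.ndarray
    method: str = "analytic"
    n_samples: int = 0
    seed: int = 0


def random_baseline(
    N: int, method: str = "analytic", n_samples: int = 10_000, seed: int = 0
) -> RandomBaseline:
    """Random-guessing overlap baseline.

    Analytic: Hypergeometric(N, t, t) mean t²/N and variance
    t·(t/N)·(1-t/N)·(N-t)/(N-1).  Monte Carlo: empirical mean/sd of the
    overlap of ``n_samples`` random permutations with a fixed reference.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    t = np.arange(1, N + 1, dtype=float)
    if method == "analytic":
        mean = t * t / N
        var = t * (t / N) * (1 - t / N) * (N - t) / (N - 1) if N > 1 else np.zeros(1)
        return RandomBaseline(N, mean, np.sqrt(np.maximum(var, 0.0)))
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        curves = np.empty((n_samples, N))
        for s in range(n_samples):
            perm_pos = np.empty(N, dtype=np.int64)
            perm_pos[rng.permutation(N)] = np.arange(1, N + 1)
            m = np.maximum(perm_pos, np.arange(1, N + 1))
            curves[s] = np.cumsum(np.bincount(m, minlength=N + 1)[1:])
        return RandomBaseline(
            N, curves.mean(axis=0), curves.std(axis=0), "montecarlo", n_samples, seed
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass
class GainCurve:
    """Per inventory size t: mean overlap, gain, normalized gain, Z-score."""

    label: str
    N: int
    O: np.ndarray
    g: np.ndarray
    G: np.ndarray
    Z: np.ndarray
    pvalue: Optional[np.ndarray] = None
    significance_method: Optional[list] = None

    @property
    def t(self) -> np.ndarray:
        return np.arange(1, self.N + 1)

    def mean_G(self, t_lo: int, t_hi: int) -> float:
        """Mean normalized gain over t in [t_lo, t_hi]."""
        if t_lo > t_hi:
            raise ValueError("empty window")
        return float(self.G[t_lo - 1 : t_hi].mean())


def gain_curve(
    pred: Prediction,
    refs: TrajectoryEnsemble,
    baseline: Optional[RandomBaseline] = None,
    label: Optional[str] = None,
) -> GainCurve:
    """Gain curve of a prediction against the normative ensemble."""
    O = mean_overlap_curve(pred, refs)
    N = len(O)
    if baseline is None:
        baseline = random_baseline(N)
    if baseline.N != N:
        raise ValueError("baseline N does not match vocabulary size")
    g = O - baseline.mean
    t = np.arange(1, N + 1)
    G = g / t
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(baseline.sd > 0, g / baseline.sd, np.nan)
    if label is None:
        first = pred.trajectories[0] if isinstance(pred, TrajectoryEnsemble) else pred
        label = first.label
    return GainCurve(label, N, O, g, G, Z)


def _direct_sampling_pvalues(
    observed: Mapping[int, float],
    refs: TrajectoryEnsemble,
    n_direct: int,
    seed: int,
) -> dict[int, float]:
    """P(random ordering's ensemble-mean overlap >= observed) per t, by
    sampling ``n_direct`` uniformly random orderings."""
    words = list(refs.trajectories[0].order)
    n = len(words)
    ts = sorted(observed)
    # F[w, k] = fraction of references placing word w within the first ts[k]
    pos = np.array([[r.positions()[w] for w in words] for r in refs])  # refs x N
    F = np.stack([(pos <= t).mean(axis=0) for t in ts], axis=1)  # N x nT
    rng = np.random.default_rng(seed)
    hits = {t: 0 for t in ts}
    done = 0
    chunk = max(1, min(n_direct, 2_000_000 // max(n, 1)))
    while done < n_direct:
        c = min(chunk, n_direct - done)
        perms = np.argsort(rng.random((c, n)), axis=1)
        for k, t in enumerate(ts):
            scores = F[perms[:, :t], k].sum(axis=1)
            hits[t] += int(np.sum(scores >= observed[t] - 1e-12))
        done += c
    return {t: hits[t] / n_direct for t in ts}


def significance(
    curve: GainCurve,
    baseline: RandomBaseline,
    refs: Optional[TrajectoryEnsemble] = None,
    gaussian_min_t: int = GAUSSIAN_MIN_T,
    alpha: float = DEFAULT_ALPHA,
    n_direct: int = DEFAULT_N_DIRECT,
    seed: int = 0,
) -> GainCurve:
    """Attach one-sided p-values to a gain curve.

    t >= ``gaussian_min_t``: Gaussian tail of Z.  Smaller t: direct
    sampling — the fraction of random orderings whose (ensemble-mean)
    overlap reaches the observed one; requires the reference ensemble.
    """
    N = curve.N
    p = np.full(N, np.nan)
    methods: list[Optional[str]] = [None] * N
    for i in range(N):
        t = i + 1
        if t >= gaussian_min_t and not math.isnan(curve.Z[i]):
            p[i] = float(norm.sf(curve.Z[i]))
            methods[i] = "gaussian"
    small_ts = [t for t in range(1, min(gaussian_min_t, N + 1)) if t <= N]
    if small_ts:
        if refs is None:
            raise ValueError("direct sampling below gaussian_min_t needs the reference ensemble")
        if n_direct < 1000:
            raise ValueError("n_direct must be >= 1000 for direct sampling")
        direct = _direct_sampling_pvalues(
            {t: curve.O[t - 1] for t in small_ts}, refs, n_direct, seed
        )
        for t, pv in direct.items():
            p[t - 1] = pv
            methods[t - 1] = "direct_sampling"
    curve.pvalue = p
    curve.significance_method = methods
    return curve


@dataclass
class StageWindows:
    """Learning-stage windows: month ranges, with an optional explicit
    inventory-size range overriding the month-derived one.

    Defaults: VELS months 19-20 (first 40 words), ELS months 20-23,
    LLS months 23-28.
    """

    stages: dict = field(
        default_factory=lambda: {
            "VELS": {"months": (19, 20), "t_range": (1, 40)},
            "ELS": {"months": (20, 23), "t_range": None},
            "LLS": {"months": (23, 28), "t_range": None},
        }
    )

    def t_ranges(self, month_to_t: Mapping[int, int], N: int) -> dict[str, tuple[int, int]]:
        """Resolve each stage to an inventory-size window [t_lo, t_hi]."""
        out = {}
        for name, spec in self.stages.items():
            if spec.get("t_range"):
                lo, hi = spec["t_range"]
            else:
                m_lo, m_hi = spec["months"]
                lo = month_to_t.get(m_lo, 1) + 1
                hi = month_to_t.get(m_hi, N)
            lo = max(1, min(int(lo), N))
            hi = max(lo, min(int(hi), N))
            out[name] = (lo, hi)
        return out


def stage_report(
    curves: Sequence[GainCurve],
    windows: StageWindows,
    month_to_t: Mapping[int, int],
):
    """Rank candidate orderings by mean normalized gain within each stage."""
    import pandas as pd

    if not curves:
        raise ValueError("no curves to rank")
    N = curves[0].N
    rows = []
    for stage, (lo, hi) in windows.t_ranges(month_to_t, N).items():
        scored = sorted(
            ((c.label, c.mean_G(lo, hi)) for c in curves), key=lambda kv: -kv[1]
        )
        for rank, (label, mg) in enumerate(scored, start=1):
            rows.append(
                {"stage": stage, "t_lo": lo, "t_hi": hi, "rank": rank, "label": label, "mean_G": mg}
            )
    return pd.DataFrame(rows)
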