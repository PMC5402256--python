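import itertools
import math

import numpy as np
import pytest

from multilex.aoa import AcquisitionTrajectory, TrajectoryEnsemble, rank_by_score
from multilex.centrality import WordScoreTable
from multilex.evaluate import (
    GainCurve,
    StageWindows,
    critical_z,
    expected_overlap_curve,
    gain_curve,
    mean_overlap,
    overlap,
    random_baseline,
    significance,
    stage_report,
)


def traj(*words, label="t", blocks=()):
    return AcquisitionTrajectory(tuple(words), label=label, tie_blocks=tuple(blocks))


class TestOverlap:
    def test_identity_gives_t(self):
        a = traj("a", "b", "c", "d")
        for t in range(1, 5):
            assert overlap(a, a, t) == t

    def test_swapped_halves(self):
        assert overlap(traj("a", "b", "c", "d"), traj("c", "d", "a", "b"), 2) == 0

    def test_out_of_range_t(self):
        a = traj("a", "b")
        with pytest.raises(ValueError):
            overlap(a, a, 0)
        with pytest.raises(ValueError):
            overlap(a, a, 3)

    def test_symmetry_and_full_overlap_at_n(self, rng):
        words = [f"w{i}" for i in range(20)]
        for _ in range(10):
            t1 = traj(*rng.permutation(words))
            t2 = traj(*rng.permutation(words))
            for t in (1, 5, 13, 20):
                assert overlap(t1, t2, t) == overlap(t2, t1, t)
                assert overlap(t1, t2, t) == len(
                    set(t1.order[:t]) & set(t2.order[:t])
                )
            assert overlap(t1, t2, 20) == 20

    def test_curve_matches_per_t_overlap(self, rng):
        words = [f"w{i}" for i in range(15)]
        t1 = traj(*rng.permutation(words))
        t2 = traj(*rng.permutation(words))
        curve = expected_overlap_curve(t1, t2)
        for t in range(1, 16):
            assert curve[t - 1] == overlap(t1, t2, t)


class TestTieExpectation:
    def test_full_tie_equals_random_baseline_mean(self):
        words = [f"w{i}" for i in range(10)]
        pred = traj(*words, blocks=[(0, 10)])
        ref = traj(*reversed(words))
        curve = expected_overlap_curve(pred, ref)
        base = random_baseline(10)
        assert np.allclose(curve, base.mean)

    def test_expected_matches_monte_carlo_resolutions(self, rng):
        scores = WordScoreTable(
            "deg", "l", {f"w{i}": float(v) for i, v in enumerate([3, 3, 3, 2, 2, 1, 1, 1, 1, 0])}
        )
        ref = TrajectoryEnsemble([traj(*rng.permutation(sorted(scores.scores)))])
        exact = gain_curve(rank_by_score(scores, "expected"), ref).O
        mc_ens = rank_by_score(scores, "resolutions", n_resolutions=5000, seed=4)
        curves = np.array(
            [expected_overlap_curve(p, ref.trajectories[0]) for p in mc_ens]
        )
        mc_mean = curves.mean(axis=0)
        se = curves.std(axis=0) / np.sqrt(len(curves))
        assert np.all(np.abs(exact - mc_mean) <= 3 * np.maximum(se, 1e-9))


class TestRandomBaseline:
    def test_t_equal_n(self):
        base = random_baseline(6)
        assert base.mean[-1] == pytest.approx(6.0)
        assert base.sd[-1] == pytest.approx(0.0)

    def test_n4_t2_exhaustive_value(self):
        base = random_baseline(4)
        assert base.mean[1] == pytest.approx(1.0)
        assert base.sd[1] == pytest.approx(math.sqrt(2 * 0.5 * 0.5 * (2 / 3)))

    @pytest.mark.parametrize("n", range(2, 8))
    def test_matches_exhaustive_permutation_enumeration(self, n):
        words = list(range(n))
        base = random_baseline(n)
        for t in range(1, n + 1):
            ref = set(words[:t])
            vals = [
                len(set(p[:t]) & ref) for p in itertools.permutations(words)
            ]
            assert base.mean[t - 1] == pytest.approx(np.mean(vals))
            assert base.sd[t - 1] == pytest.approx(np.std(vals), abs=1e-12)

    def test_analytic_matches_monte_carlo(self):
        """Analytic mean/sd agree with 10k-permutation Monte Carlo at every t.

        Per-t deviations are standardized by the exact SE of each estimator
        (delta method with the hypergeometric fourth moment for the sample
        sd — the overlap is far from normal at extreme t).  The 3-SE
        agreement level is applied familywise across the ~196 simultaneous
        comparisons (Šidák, per-comparison z = 4.06): a wrong formula
        deviates systematically by tens of SEs, while a correct one produces
        a ~3-SE excursion at some t for a quarter of all seeds.
        """
        from scipy.stats import hypergeom, norm

        n = 100
        analytic = random_baseline(n)
        mc = random_baseline(n, method="montecarlo", n_samples=10_000, seed=3)
        k = mc.n_samples
        n_comparisons = 2 * (n - 1)
        alpha_family = 2 * norm.sf(3.0)
        zmax = norm.isf((1 - (1 - alpha_family) ** (1 / n_comparisons)) / 2)
        for t in range(1, n):
            sd = analytic.sd[t - 1]
            if sd == 0:
                continue
            z_mean = abs(analytic.mean[t - 1] - mc.mean[t - 1]) / (sd / math.sqrt(k))
            assert z_mean <= zmax
            kurt = hypergeom(n, t, t).stats(moments="k")
            mu4 = (kurt + 3) * sd**4
            se_sd = math.sqrt(max(mu4 - sd**4, 0.0) / k) / (2 * sd)
            assert abs(sd - mc.sd[t - 1]) <= zmax * max(se_sd, 1e-12)


class TestGainCurve:
    def test_perfect_prediction_normalized_gain(self):
        words = [f"w{i}" for i in range(50)]
        p = traj(*words)
        curve = gain_curve(p, TrajectoryEnsemble([traj(*words)]))
        for t in range(1, 50):
            assert curve.G[t - 1] == pytest.approx(1 - t / 50)

    def test_worked_three_word_instance(self):
        scores = WordScoreTable("degree", "association", {"food": 62, "water": 45, "eat": 20})
        pred = rank_by_score(scores)
        refs = TrajectoryEnsemble([traj("food", "water", "eat")])
        curve = gain_curve(pred, refs)
        assert list(curve.O) == [1, 2, 3]
        for t in (1, 2, 3):
            assert curve.g[t - 1] == pytest.approx(t - t * t / 3)

    def test_random_prediction_gain_near_zero(self, rng):
        words = [f"w{i}" for i in range(100)]
        ref = TrajectoryEnsemble([traj(*rng.permutation(words))])
        gs = []
        for _ in range(200):
            p = traj(*rng.permutation(words))
            gs.append(gain_curve(p, ref).g[49])
        base = random_baseline(100)
        assert abs(np.mean(gs)) < 3 * base.sd[49] / np.sqrt(200)

    def test_mean_overlap_over_identical_ensemble(self):
        a = traj("a", "b", "c", "d")
        b = traj("b", "a", "d", "c")
        ens = TrajectoryEnsemble([b, b, b])
        assert mean_overlap(a, ens, 2) == overlap(a, b, 2)

    def test_gain_bounds(self, rng):
        words = [f"w{i}" for i in range(30)]
        base = random_baseline(30)
        p = traj(*rng.permutation(words))
        c = gain_curve(p, TrajectoryEnsemble([traj(*rng.permutation(words))]), base)
        t = np.arange(1, 31)
        assert np.all(c.G <= 1 - base.mean / t + 1e-12)
        assert np.all(c.G >= -base.mean / t - 1e-12)


class TestSignificance:
    def test_critical_z_two_decimals(self):
        assert round(critical_z(0.025), 2) == 1.96

    def test_zero_z_gives_half(self):
        words = [f"w{i}" for i in range(80)]
        curve = GainCurve("x", 80, np.zeros(80), np.zeros(80), np.zeros(80), np.zeros(80))
        base = random_baseline(80)
        refs = TrajectoryEnsemble([traj(*words)])
        out = significance(curve, base, refs, gaussian_min_t=60, n_direct=1000)
        assert out.pvalue[69] == pytest.approx(0.5)
        assert out.significance_method[69] == "gaussian"
        assert out.significance_method[10] == "direct_sampling"

    def test_perfect_prediction_tiny_pvalue(self):
        words = [f"w{i}" for i in range(100)]
        p = traj(*words)
        base = random_baseline(100)
        curve = gain_curve(p, TrajectoryEnsemble([traj(*words)]), base)
        out = significance(curve, base, TrajectoryEnsemble([traj(*words)]), n_direct=1000)
        assert out.pvalue[69] < 1e-6

    def test_direct_sampling_p_is_one_at_full_inventory(self):
        words = [f"w{i}" for i in range(30)]
        p = traj(*words)
        refs = TrajectoryEnsemble([traj(*reversed(words))])
        base = random_baseline(30)
        curve = gain_curve(p, refs, base)
        out = significance(curve, base, refs, gaussian_min_t=60, n_direct=1000, seed=1)
        assert out.pvalue[29] == pytest.approx(1.0)  # every ordering overlaps fully

    def test_direct_sampling_requires_refs(self):
        curve = GainCurve("x", 30, np.zeros(30), np.zeros(30), np.zeros(30), np.zeros(30))
        with pytest.raises(ValueError, match="reference ensemble"):
            significance(curve, random_baseline(30))


class TestStageReport:
    def _curve(self, label, gvals):
        n = len(gvals)
        g = np.asarray(gvals, dtype=float)
        t = np.arange(1, n + 1)
        return GainCurve(label, n, g * t + t * t / n, g * t, g, np.zeros(n))

    def test_single_curve_ranks_first_everywhere(self):
        c = self._curve("only", np.linspace(0.5, 0.1, 60))
        rep = stage_report([c], StageWindows(), {19: 5, 20: 10, 23: 30, 28: 55})
        assert set(rep["label"]) == {"only"}
        assert all(rep["rank"] == 1)

    def test_uniformly_dominant_curve_wins_all_stages(self):
        hi = self._curve("hi", np.full(60, 0.4))
        lo = self._curve("lo", np.full(60, 0.1))
        rep = stage_report([hi, lo], StageWindows(), {19: 5, 20: 10, 23: 30, 28: 55})
        winners = rep[rep["rank"] == 1]
        assert set(winners["label"]) == {"hi"}

    def test_stage_specific_winner(self):
        early = np.concatenate([np.full(20, 0.5), np.full(40, 0.05)])
        late = np.concatenate([np.full(20, 0.1), np.full(40, 0.3)])
        rep = stage_report(
            [self._curve("early", early), self._curve("late", late)],
            StageWindows(),
            {19: 5, 20: 10, 23: 30, 28: 55},
        )
        vels = rep[(rep["stage"] == "VELS") & (rep["rank"] == 1)]["label"].iloc[0]
        lls = rep[(rep["stage"] == "LLS") & (rep["rank"] == 1)]["label"].iloc[0]
        assert vels == "early" and lls == "late"


class TestZCalibration:
    def test_z_of_random_predictions_standard_normal_at_large_t(self, rng):
        # moderate-size version of the calibration check: Z at t=80, N=150
        words = [f"w{i}" for i in range(150)]
        refs = TrajectoryEnsemble([traj(*rng.permutation(words))])
        base = random_baseline(150)
        zs = [
            gain_curve(traj(*rng.permutation(words)), refs, base).Z[79]
            for _ in range(300)
        ]
        assert abs(np.mean(zs)) < 0.2
        assert abs(np.std(zs) - 1.0) < 0.15
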