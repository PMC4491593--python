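from math import comb

import numpy as np
import pytest
from scipy import stats

from odorcap import models, protocol
from odorcap.errors import (
    InfeasibleDesignError,
    NoCriticalDistanceError,
    ProtocolError,
)
from odorcap.mixtures import ModelKind
from odorcap.protocol import (
    CriticalDistance,
    DiscriminationCurve,
    class_fraction,
    critical_distance,
    discrimination_curve,
    majority_threshold,
    odd_man_out_trial,
    pair_discriminability,
)

RING_NOISE = models.NoiseConfig(sigma_ring=0.4)


def microbe_disc_prob(N: int, O: int) -> float:
    """Exact probability that two (N, O)-mixtures land in different categories.

    Conditions on the shared-block sum; the two unshared blocks are then
    independent sums of N - O fair +-1 variables.
    """

    def sum_pmf(n):
        return {2 * k - n: comb(n, k) / 2**n for k in range(n + 1)}

    def cat_probs(shift, n):
        out = [0.0, 0.0, 0.0]  # yum, meh, yuck
        for s, p in sum_pmf(n).items():
            t = s + shift
            out[0 if t > 2 else (1 if t >= -2 else 2)] += p
        return out

    total = 0.0
    for shared_sum, p_shared in sum_pmf(O).items():
        y, m, u = cat_probs(shared_sum, N - O)
        total += p_shared * (1 - (y * y + m * m + u * u))
    return total


class TestOddManOutTrial:
    def test_microbe_routed_here_raises(self, rng):
        with pytest.raises(ProtocolError):
            odd_man_out_trial("microbe", 0, 2, RING_NOISE, rng)

    def test_identical_mixtures_are_chance(self):
        rng = np.random.default_rng(21)
        hits = sum(
            odd_man_out_trial("ring", 1.0, 1.0, RING_NOISE, rng).correct
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(1 / 3, abs=0.015)

    def test_noiseless_distinct_always_correct(self):
        rng = np.random.default_rng(22)
        noise = models.NoiseConfig(sigma_ring=1e-300, sigma_rgb=1e-300)
        for _ in range(50):
            assert odd_man_out_trial("ring", 0.3, 2.0, noise, rng).correct
            assert odd_man_out_trial(
                "color", np.zeros(3), np.ones(3), noise, rng
            ).correct

    def test_ring_opposite_mixtures_nearly_always_correct(self):
        rng = np.random.default_rng(23)
        hits = sum(
            odd_man_out_trial("ring", 0.0, np.pi, RING_NOISE, rng).correct
            for _ in range(10_000)
        )
        # MC oracle: failure needs the duplicate-pair distance (~sigma*sqrt(2))
        # to exceed a cross distance of ~pi; measured rate is ~0.997
        assert hits / 10_000 > 0.99

    def test_record_fields(self, rng):
        rec = odd_man_out_trial("ring", 0.0, 2.0, RING_NOISE, rng)
        assert rec.target_position in (0, 1, 2)
        assert rec.chosen_odd in (0, 1, 2)
        assert rec.correct == (rec.chosen_odd == rec.target_position)


class TestPairDiscriminability:
    def test_microbe_yum_vs_yuck(self, rng):
        res = pair_discriminability("microbe", 4, -4, rng=rng)
        assert res.discriminable

    def test_microbe_both_meh(self, rng):
        assert not pair_discriminability("microbe", 0, 2, rng=rng).discriminable

    def test_majority_threshold(self):
        assert majority_threshold(26) == 14
        assert majority_threshold(25) == 13

    def test_identical_color_mixtures_rarely_pass(self, color_noise):
        # exact oracle: P(Binomial(26, 1/3) >= 14)
        expected = float(stats.binom.sf(13, 26, 1 / 3))
        assert expected == pytest.approx(0.0248, abs=5e-4)
        rng = np.random.default_rng(24)
        v = np.tile([0.2, 0.3, 0.1], (3000, 1))
        nc = protocol._ncorrect_batch(ModelKind.COLOR, v, v.copy(), color_noise, 26, rng)
        frac = np.mean(nc >= 14)
        assert frac == pytest.approx(expected, abs=0.01)

    def test_scalar_and_batch_paths_agree(self, color_noise):
        # same statistics from the scalar reference path and the batch engine
        rng = np.random.default_rng(25)
        pa, pb = np.array([0.0, 0.0, 0.0]), np.array([0.012, 0.0, 0.0])
        scalar = np.mean(
            [
                pair_discriminability("color", pa, pb, color_noise, rng=rng).n_correct
                for _ in range(400)
            ]
        )
        batch = protocol._ncorrect_batch(
            ModelKind.COLOR, np.tile(pa, (400, 1)), np.tile(pb, (400, 1)),
            color_noise, 26, rng,
        ).mean()
        se = 26 * 0.5 / np.sqrt(400)  # generous bound on either mean
        assert abs(scalar - batch) < 4 * se


class TestClassFraction:
    def test_microbe_disjoint_class_near_analytic(self):
        rng = np.random.default_rng(26)
        oracle = microbe_disc_prob(30, 0)
        assert oracle == pytest.approx(0.6566, abs=5e-4)
        sums = rng.choice([-1, 1], size=(4000, 2, 30)).sum(axis=2)
        frac = class_fraction("microbe", [tuple(row) for row in sums], rng=rng)
        assert frac == pytest.approx(oracle, abs=0.03)

    def test_fully_overlapping_microbe_class_is_zero(self, rng):
        pairs = [(s, s) for s in rng.integers(-30, 31, size=50)]
        assert class_fraction("microbe", pairs, rng=rng) == 0.0


class TestDiscriminationCurve:
    def test_microbe_curve_matches_exact_oracle(self):
        overlaps = [0, 5, 10, 15, 20, 25, 30]
        curve = discrimination_curve(
            "microbe", N=30, overlaps=overlaps, n_replicates=300, rng=31
        )
        for O, mean in zip(curve.overlaps, curve.mean_fraction):
            assert mean == pytest.approx(microbe_disc_prob(30, int(O)), abs=0.02)

    def test_same_seed_identical_curve(self, color_noise):
        kw = dict(N=20, overlaps=[0, 10, 19], n_replicates=30, noise=color_noise)
        a = discrimination_curve("color", rng=5, **kw)
        b = discrimination_curve("color", rng=5, **kw)
        assert np.array_equal(a.mean_fraction, b.mean_fraction)
        assert np.array_equal(a.sd_fraction, b.sd_fraction)
        c = discrimination_curve("color", rng=6, **kw)
        assert not np.array_equal(a.mean_fraction, c.mean_fraction)

    def test_ring_curve_decreasing_in_overlap(self):
        curve = discrimination_curve(
            "ring", N=30, overlaps=[0, 10, 20, 28, 30], n_replicates=150,
            noise=RING_NOISE, rng=32,
        )
        spread = 2 * curve.sd_fraction[:-1] / np.sqrt(curve.n_replicates)
        assert np.all(np.diff(curve.mean_fraction) < spread + 1e-9)

    def test_infeasible_overlaps_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="infeasible"):
            curve = discrimination_curve(
                "microbe", N=30, overlaps=[0, 15, 30], C=59, n_replicates=5, rng=33
            )
        assert curve.overlaps.tolist() == [15, 30]

    def test_entirely_infeasible_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(InfeasibleDesignError):
                discrimination_curve(
                    "microbe", N=30, overlaps=[0], C=40, n_replicates=5, rng=34
                )

    def test_color_without_sigma_raises(self):
        with pytest.raises(ProtocolError):
            discrimination_curve("color", N=10, n_replicates=2, rng=35)

    def test_fresh_vectors_only_for_color(self):
        with pytest.raises(ProtocolError):
            discrimination_curve(
                "ring", N=10, n_replicates=2, rng=36, fresh_vectors=True
            )

    def test_pair_stats_collected(self):
        curve = discrimination_curve(
            "ring", N=10, overlaps=[0, 5, 10], n_replicates=4,
            noise=RING_NOISE, rng=37, collect_pair_stats=True,
        )
        assert curve.pair_correct_fraction.shape == (4, 3, 20)
        assert np.all((curve.pair_correct_fraction >= 0) & (curve.pair_correct_fraction <= 1))


def make_curve(overlaps, means, N=30):
    overlaps = np.asarray(overlaps)
    return DiscriminationCurve(
        model_kind=ModelKind.MICROBE,
        N=N,
        overlaps=overlaps,
        mean_fraction=np.asarray(means, float),
        sd_fraction=np.zeros(len(overlaps)),
        n_replicates=1,
    )


class TestCriticalDistance:
    def test_step_curve_interpolates_midpoint(self):
        overlaps = list(range(31))
        means = [1.0 if o < 10 else 0.0 for o in overlaps]
        crit = critical_distance(make_curve(overlaps, means))
        assert crit.crossing_overlap == pytest.approx(9.5)
        assert crit.D == pytest.approx(20.5)
        assert crit.D_int == 20  # banker's rounding of 20.5

    def test_linear_interpolation_between_grid_points(self):
        crit = critical_distance(make_curve([0, 10, 20], [0.9, 0.6, 0.2]))
        # crossing at O = 10 + 10 * (0.6 - 0.5) / (0.6 - 0.2) = 12.5
        assert crit.crossing_overlap == pytest.approx(12.5)
        assert crit.D == pytest.approx(17.5)

    def test_curve_above_level_everywhere_gives_distance_one(self):
        crit = critical_distance(make_curve([0, 10, 20, 29, 30], [1, 1, 0.95, 0.8, 0.02]))
        assert crit.D == 1.0

    def test_curve_below_level_raises(self):
        with pytest.raises(NoCriticalDistanceError):
            critical_distance(make_curve([0, 10], [0.4, 0.2]))

    def test_custom_level(self):
        crit = critical_distance(make_curve([0, 10], [1.0, 0.0]), level=0.9)
        assert crit.crossing_overlap == pytest.approx(1.0)
        assert isinstance(crit, CriticalDistance)
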