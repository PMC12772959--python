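"""Sinkhorn divergence, cardinality binarization, bootstrap null, LOOCV."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from spatmap.evaluation import (
    SpatialDistribution,
    binarize_to_cardinality,
    bootstrap_tail_probability,
    reconstruction_error,
    sinkhorn_divergence,
)
from spatmap.projection import SpatialField


def exact_transport_cost(a: SpatialDistribution, b: SpatialDistribution) -> float:
    """Independent oracle: linear-program optimal transport (half sq. Eucl.)."""
    an, bn = a.normalized(), b.normalized()
    n, m = an.points.shape[0], bn.points.shape[0]
    diff = an.points[:, None, :] - bn.points[None, :, :]
    C = 0.5 * (diff**2).sum(-1)
    A_eq = []
    for i in range(n):
        r = np.zeros((n, m)); r[i, :] = 1
        A_eq.append(r.ravel())
    for j in range(m):
        r = np.zeros((n, m)); r[:, j] = 1
        A_eq.append(r.ravel())
    res = linprog(
        C.ravel(), A_eq=np.array(A_eq),
        b_eq=np.concatenate([an.weights, bn.weights]),
        bounds=(0, None), method="highs",
    )
    assert res.status == 0
    return res.fun


def rand_dist(rng, n, extent=20.0):
    return SpatialDistribution(
        rng.uniform(0, extent, (n, 2)), rng.random(n) + 0.05
    )


class TestSpatialDistribution:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            SpatialDistribution(np.empty((0, 2)), np.empty(0))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            SpatialDistribution(np.zeros((1, 2)), np.array([-1.0]))


class TestBinarizeToCardinality:
    def test_all_nonzero_bins_when_n_matches(self):
        vals = np.array([[0.0, 1.0], [2.0, 3.0]])
        d = binarize_to_cardinality(SpatialField(vals), 3)
        assert len(d.points) == 3
        assert np.allclose(d.weights, 1 / 3)

    def test_distinct_values_pick_argmax(self):
        vals = np.arange(9.0).reshape(3, 3)
        d = binarize_to_cardinality(SpatialField(vals), 3)
        assert {tuple(p) for p in d.points} == {(2, 2), (2, 1), (2, 0)}

    def test_tie_break_is_lexicographic(self):
        vals = np.zeros((2, 4))
        vals[:, :2] = 5.0
        vals[:, 2:] = 5.0  # 8-way tie
        d = binarize_to_cardinality(SpatialField(vals), 2)
        assert {tuple(p) for p in d.points} == {(0, 0), (0, 1)}

    def test_out_of_range_cardinality_rejected(self):
        f = SpatialField(np.eye(3))
        with pytest.raises(ValueError):
            binarize_to_cardinality(f, 0)
        with pytest.raises(ValueError):
            binarize_to_cardinality(f, 4)


class TestSinkhornDivergence:
    def test_self_divergence_is_zero(self, rng):
        d = rand_dist(rng, 9)
        assert abs(sinkhorn_divergence(d, d, blur=1.0)) < 1e-6

    def test_two_point_masses_give_half_squared_distance(self):
        a = SpatialDistribution(np.array([[0.0, 0.0]]), np.array([1.0]))
        b = SpatialDistribution(np.array([[3.0, 4.0]]), np.array([1.0]))
        assert sinkhorn_divergence(a, b, blur=0.05) == pytest.approx(12.5, rel=1e-3)

    def test_symmetry(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            a, b = rand_dist(r, 7), rand_dist(r, 5)
            assert sinkhorn_divergence(a, b, blur=1.5) == pytest.approx(
                sinkhorn_divergence(b, a, blur=1.5), abs=1e-6
            )

    def test_nonnegative_on_fuzzed_inputs(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            a, b = rand_dist(r, 6), rand_dist(r, 6)
            assert sinkhorn_divergence(a, b, blur=2.0) >= -1e-6

    def test_matches_exact_transport_at_small_blur(self):
        """<= 10-point instances agree with the LP oracle within 5%.

        Points snap to a unit lattice so the minimum inter-point distance
        (and hence the blur bound) stays bounded away from zero.
        """
        def lattice_dist(r, n, offset):
            flat = r.choice(20 * 20, size=n, replace=False)
            pts = np.stack([flat // 20, flat % 20], axis=-1) + offset
            return SpatialDistribution(pts.astype(float), r.random(n) + 0.1)

        for seed in range(5):
            r = np.random.default_rng(seed)
            a = lattice_dist(r, int(r.integers(3, 8)), 0.0)
            b = lattice_dist(r, int(r.integers(3, 8)), 0.5)
            pts = np.vstack([a.points, b.points])
            dmin = min(
                np.hypot(*(pts[i] - pts[j]))
                for i, j in itertools.combinations(range(len(pts)), 2)
            )
            blur = 0.1 * dmin
            S = sinkhorn_divergence(a, b, blur=blur, tol=1e-7, max_iter=200000)
            exact = exact_transport_cost(a, b)
            assert S == pytest.approx(exact, rel=0.05)

    def test_invalid_blur_rejected(self, rng):
        with pytest.raises(ValueError):
            sinkhorn_divergence(rand_dist(rng, 3), rand_dist(rng, 3), blur=0)


class TestReconstructionError:
    def test_perfect_reconstruction_is_zero(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:6, 3:6] = True
        field = SpatialField(mask.astype(float))
        assert reconstruction_error(mask, field, blur=1.0) < 1e-6

    def test_divergence_grows_with_translation(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:10, 5:10] = True
        divs = []
        for shift in range(0, 30, 3):
            field_vals = np.zeros((40, 40))
            field_vals[5:10, 5 + shift:10 + shift] = 1.0
            divs.append(
                reconstruction_error(mask, SpatialField(field_vals), blur=1.0)
            )
        assert all(b >= a - 1e-6 for a, b in zip(divs, divs[1:]))
        assert divs[-1] > divs[0]

    def test_one_bin_shift_matches_transport_oracle(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[4, 4:7] = True
        field_vals = np.zeros((12, 12))
        field_vals[5, 4:7] = 1.0  # shifted one row
        measured = SpatialDistribution.from_mask(mask)
        inferred = binarize_to_cardinality(SpatialField(field_vals), 3)
        S = sinkhorn_divergence(measured, inferred, blur=0.05)
        assert S == pytest.approx(exact_transport_cost(measured, inferred), rel=0.05)

    def test_empty_measured_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_error(
                np.zeros((5, 5), dtype=bool), SpatialField(np.ones((5, 5)))
            )


class TestBootstrapTail:
    def test_extreme_observed_values(self, rng):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:14, 10:14] = True
        measured = SpatialDistribution.from_mask(mask)
        lo = bootstrap_tail_probability(measured, -1.0, 100, (32, 32), seed=0)
        assert lo == 0.0
        hi = bootstrap_tail_probability(measured, 1e9, 100, (32, 32), seed=0)
        assert hi == 1.0

    def test_deterministic_given_seed(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:8, 4:8] = True
        measured = SpatialDistribution.from_mask(mask)
        t1 = bootstrap_tail_probability(measured, 50.0, 100, (32, 32), seed=3)
        t2 = bootstrap_tail_probability(measured, 50.0, 100, (32, 32), seed=3)
        assert t1 == t2

    def test_tail_monotone_in_observed_divergence(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:9, 4:9] = True
        measured = SpatialDistribution.from_mask(mask)
        tails = [
            bootstrap_tail_probability(measured, d, 150, (32, 32), seed=5)
            for d in (10.0, 100.0, 300.0, 600.0)
        ]
        assert tails == sorted(tails)

    def test_null_samples_calibrated_against_themselves(self, rng):
        """Uniform-sample divergences land at roughly uniform tail ranks."""
        from spatmap.evaluation import _batched_null_divergences

        mask = np.zeros((32, 32), dtype=bool)
        mask[8:16, 8:16] = True
        measured = SpatialDistribution.from_mask(mask)
        null = _batched_null_divergences(
            measured, 64, 200, (32, 32), np.random.default_rng(0), blur=2.0
        )
        extra = _batched_null_divergences(
            measured, 64, 50, (32, 32), np.random.default_rng(1), blur=2.0
        )
        ranks = np.array([(null <= d).mean() for d in extra])
        # Kolmogorov-Smirnov distance from uniform at n = 50
        grid_q = np.sort(ranks)
        ks = np.max(np.abs(grid_q - (np.arange(1, 51)) / 50))
        assert ks < 0.25

    def test_too_few_replicates_rejected(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            bootstrap_tail_probability(
                SpatialDistribution.from_mask(mask), 1.0, 10, (8, 8)
            )
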