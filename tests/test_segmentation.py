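import numpy as np
import pytest

from lapcell.io import VolumeStack
from lapcell.saliency import NoSeedError, SeedSet
from lapcell.segmentation import (SegmentationConfig, build_affinity,
                                  downsample, segment, solve_random_walker,
                                  tukey_weight, upsample_probability,
                                  UpsampleParams)
from lapcell.synth import SyntheticCellSpec, f_measure, make_cell_volume


def _seed_set(fg, bg):
    return SeedSet(fg=fg, bg=bg, mu_fg=0.0, mu_bg=0.0, thresholds=(0, 0, 0.5, 0.5))


class TestAffinity:
    def test_equal_intensity_unit_spacing_weight(self):
        """6-neighbours at equal intensity, σ_S = 1: A_ij = exp(−1)."""
        stack = VolumeStack(np.full((2, 1, 1), 0.3))
        g = build_affinity(stack, sigma_S=1.0, sigma_I=0.01)
        off = -g.laplacian.toarray()[0, 1]
        np.testing.assert_allclose(off, np.exp(-1.0), rtol=1e-12)

    def test_laplacian_rows_sum_to_zero(self, rng):
        g = build_affinity(VolumeStack(rng.random((4, 3, 3))))
        rowsum = np.asarray(g.laplacian.sum(axis=1)).ravel()
        np.testing.assert_allclose(rowsum, 0.0, atol=1e-14)
        # symmetric, non-positive off-diagonals
        L = g.laplacian.toarray()
        np.testing.assert_allclose(L, L.T, atol=1e-15)
        assert np.all(L - np.diag(np.diag(L)) <= 0)

    def test_matches_per_edge_brute_force(self):
        intens = np.array([[[0.1], [0.9]], [[0.4], [0.5]]])
        sS, sI = 2.0, 0.05
        g = build_affinity(VolumeStack(intens), sS, sI)
        L = g.laplacian.toarray()
        n = 4
        pos = [(i, j, 0) for i in range(2) for j in range(2)]
        A = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                d = np.abs(np.array(pos[a]) - np.array(pos[b]))
                if d.sum() == 1:  # 6-neighbours
                    di = intens[pos[a]] - intens[pos[b]]
                    A[a, b] = np.exp(-d.sum() / sS - di ** 2 / sI)
        Lref = np.diag(A.sum(axis=1)) - A
        np.testing.assert_allclose(L, Lref, atol=1e-14)

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            build_affinity(VolumeStack(np.zeros((2, 2, 2))), sigma_S=0.0)


class TestRandomWalker:
    def test_three_node_chain_midpoint_half(self):
        stack = VolumeStack(np.zeros((3, 1, 1)))
        g = build_affinity(stack)
        fg = np.zeros((3, 1, 1), bool); fg[0] = True
        bg = np.zeros((3, 1, 1), bool); bg[2] = True
        x = solve_random_walker(g, _seed_set(fg, bg))
        np.testing.assert_allclose(x[1, 0, 0], 0.5, atol=1e-12)

    def test_class_probabilities_complementary(self, rng):
        """fg and bg harmonic solutions with complementary boundary data sum
        to one everywhere."""
        stack = VolumeStack(rng.random((5, 4, 3)))
        g = build_affinity(stack)
        fg = np.zeros((5, 4, 3), bool); fg[0, 0, 0] = True
        bg = np.zeros((5, 4, 3), bool); bg[4, 3, 2] = True
        x_fg = solve_random_walker(g, _seed_set(fg, bg))
        x_bg = solve_random_walker(g, _seed_set(bg, fg))
        np.testing.assert_allclose(x_fg + x_bg, 1.0, atol=1e-9)

    def test_matches_dense_oracle(self, rng):
        stack = VolumeStack(rng.random((6, 6, 3)))
        g = build_affinity(stack)
        fg = np.zeros((6, 6, 3), bool); fg[rng.integers(6), rng.integers(6), 0] = True
        bg = np.zeros((6, 6, 3), bool); bg[rng.integers(6), rng.integers(6), 2] = True
        x = solve_random_walker(g, _seed_set(fg, bg)).ravel()
        L = g.laplacian.toarray()
        seeded = (fg | bg).ravel()
        xm = fg.ravel()[seeded].astype(float)
        xu = np.linalg.solve(L[np.ix_(~seeded, ~seeded)],
                             -L[np.ix_(~seeded, seeded)] @ xm)
        ref = np.empty(len(x)); ref[seeded] = xm; ref[~seeded] = xu
        assert np.abs(x - ref).max() < 1e-8

    def test_maximum_principle(self, rng):
        stack = VolumeStack(rng.random((6, 5, 4)))
        g = build_affinity(stack, sigma_I=0.005)
        fg = rng.random((6, 5, 4)) < 0.1
        bg = (rng.random((6, 5, 4)) < 0.1) & ~fg
        if not fg.any() or not bg.any():
            pytest.skip("degenerate seed draw")
        x = solve_random_walker(g, _seed_set(fg, bg))
        assert x.min() >= 0.0 and x.max() <= 1.0

    def test_invariant_to_uniform_weight_scaling(self, rng):
        data = rng.random((5, 5, 3))
        g1 = build_affinity(VolumeStack(data))
        g2 = build_affinity(VolumeStack(data))
        g2.laplacian = g2.laplacian * 7.3
        fg = np.zeros((5, 5, 3), bool); fg[0, 0, 0] = True
        bg = np.zeros((5, 5, 3), bool); bg[4, 4, 2] = True
        x1 = solve_random_walker(g1, _seed_set(fg, bg))
        x2 = solve_random_walker(g2, _seed_set(fg, bg))
        np.testing.assert_allclose(x1, x2, atol=1e-9)

    def test_residual_below_tolerance(self, rng):
        stack = VolumeStack(rng.random((6, 6, 3)))
        g = build_affinity(stack)
        fg = np.zeros((6, 6, 3), bool); fg[1, 1, 1] = True
        bg = np.zeros((6, 6, 3), bool); bg[5, 5, 0] = True
        x = solve_random_walker(g, _seed_set(fg, bg)).ravel()
        res = g.laplacian @ x
        un = ~(fg | bg).ravel()
        assert np.abs(res[un]).max() < 1e-8


class TestDownsample:
    def test_rate_one_identity(self, rng):
        stack = VolumeStack(rng.random((8, 8, 3)))
        out = downsample(stack, 1)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_constant_stays_constant(self):
        out = downsample(VolumeStack(np.full((16, 16, 4), 0.42)), 4)
        np.testing.assert_allclose(out.data, 0.42, atol=1e-14)

    def test_linear_ramp_matches_analytic_bilinear(self):
        nx = 16
        ramp = np.tile(np.arange(nx, dtype=float)[:, None, None], (1, 8, 3))
        out = downsample(VolumeStack(ramp), 2)
        expect = np.arange(out.shape[0]) * 2 + 0.5  # block-centred samples
        np.testing.assert_allclose(out.data[:, 0, 0], expect, atol=1e-12)

    def test_z_untouched_and_spacing_updated(self, rng):
        stack = VolumeStack(rng.random((16, 16, 5)), (0.16, 0.16, 0.5))
        out = downsample(stack, 4)
        assert out.shape == (4, 4, 5)
        np.testing.assert_allclose(out.spacing, (0.64, 0.64, 0.5))

    def test_excessive_rate_rejected(self):
        with pytest.raises(ValueError):
            downsample(VolumeStack(np.zeros((4, 4, 2))), 8)


class TestUpsampleWeighting:
    def test_tukey_closed_forms(self):
        """w = 1 at zero deviation; 0 beyond τ; (1 − 1/4)² = 0.5625 at τ/2."""
        tau = 0.3
        assert tukey_weight(0.0, tau) == 1.0
        assert tukey_weight(tau * 1.0001, tau) == 0.0
        np.testing.assert_allclose(tukey_weight(tau / 2, tau), 0.5625, rtol=1e-15)
        # boundary: |d| = τ included with weight 0
        np.testing.assert_allclose(tukey_weight(tau, tau), 0.0, atol=1e-15)

    def test_upsampled_labels_follow_intensity_weights(self, rng):
        # two-phase image: bright block on dark background
        data = np.full((16, 16, 4), 0.05)
        data[4:12, 4:12, 1:3] = 0.95
        stack = VolumeStack(data)
        p_down = np.zeros((4, 4, 4))
        p_down[1:3, 1:3, :] = 1.0
        fg = np.zeros((4, 4, 4), bool); fg[2, 2, 2] = True
        bg = np.zeros((4, 4, 4), bool); bg[0, 0, 0] = True
        seeds = SeedSet(fg, bg, 0.95, 0.05, (0, 0, 0.9, 0.1))
        labels, qf, qb = upsample_probability(p_down, stack, seeds, 4,
                                              UpsampleParams(tau_fg=0.2, tau_bg=0.2))
        assert labels[8, 8, 2] and not labels[0, 0, 0]


class TestSegmentChain:
    def test_clean_sphere_f_measure(self):
        spec = SyntheticCellSpec(body_radii=(16, 16, 16), n_protrusions=0,
                                 noise_sigma=0.0, blur_sigma=0.0, rng_seed=1)
        stack, truth = make_cell_volume(spec)
        pred = segment(stack)
        assert f_measure(pred, truth) >= 0.99

    def test_noisy_dim_cell_f_measure(self):
        spec = SyntheticCellSpec(noise_sigma=0.1, interior_dimming=0.5, rng_seed=0)
        stack, truth = make_cell_volume(spec)
        assert f_measure(segment(stack), truth) >= 0.9

    def test_deterministic(self):
        spec = SyntheticCellSpec(noise_sigma=0.1, rng_seed=3)
        stack, _ = make_cell_volume(spec)
        m1 = segment(stack)
        m2 = segment(stack)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_featureless_stack_raises_no_seed(self):
        """Uniform saliency (std = 0) leaves the strict first-level
        thresholds unsatisfied: the no-seed error must surface."""
        stack = VolumeStack(np.full((32, 32, 8), 0.5))
        with pytest.raises(NoSeedError):
            segment(stack)

    def test_invalid_config_rejected_before_compute(self):
        with pytest.raises(ValueError):
            SegmentationConfig(tau_fg=-1.0).validate()
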