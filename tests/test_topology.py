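import numpy as np
import pytest

from lapcell.io import BinaryVolume
from lapcell.synth import SyntheticCellSpec, make_cell_mask
from lapcell.topology import (MarginField, SinglePhaseError,
                              UnfixableTopologyError, boundary_voxels,
                              compute_margins, detect_protrusions,
                              embedding_energy, euler_characteristic,
                              fix_topology, is_spherical, solve_embedding)


def brute_force_euler(mask):
    """Explicit cubical-complex cell enumeration."""
    verts, edges, faces = set(), set(), set()
    cells = 0
    for i, j, k in np.argwhere(mask):
        cells += 1
        cs = [(i + a, j + b, k + c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        verts.update(cs)
        for a in (0, 1):
            for b in (0, 1):
                edges.add(frozenset({(i, j + a, k + b), (i + 1, j + a, k + b)}))
                edges.add(frozenset({(i + a, j, k + b), (i + a, j + 1, k + b)}))
                edges.add(frozenset({(i + a, j + b, k), (i + a, j + b, k + 1)}))
        for a in (0, 1):
            faces.add(frozenset({(i + a, j, k), (i + a, j + 1, k),
                                 (i + a, j, k + 1), (i + a, j + 1, k + 1)}))
            faces.add(frozenset({(i, j + a, k), (i + 1, j + a, k),
                                 (i, j + a, k + 1), (i + 1, j + a, k + 1)}))
            faces.add(frozenset({(i, j, k + a), (i + 1, j, k + a),
                                 (i, j + 1, k + a), (i + 1, j + 1, k + a)}))
    return len(verts) - len(edges) + len(faces) - cells


class TestEulerCharacteristic:
    def test_solid_ball(self, ball_mask):
        assert euler_characteristic(ball_mask) == 1

    def test_two_disjoint_balls_additive(self, ball_mask):
        b = ball_mask.mask
        two = np.zeros((60, 21, 21), bool)
        two[:21] = b
        two[30:51] = b
        assert euler_characteristic(two) == 2

    def test_torus_matches_brute_force(self, torus_mask):
        assert euler_characteristic(torus_mask) == 0
        # independent oracle on a smaller torus
        g = np.ogrid[0:17, 0:17, 0:9]
        d = (np.sqrt((g[0] - 8.0) ** 2 + (g[1] - 8.0) ** 2) - 5.0) ** 2 + (g[2] - 4.0) ** 2
        small = d <= 4.0
        assert euler_characteristic(small) == brute_force_euler(small) == 0

    def test_random_masks_match_brute_force(self, rng):
        for _ in range(5):
            m = rng.random((5, 5, 5)) < 0.4
            assert euler_characteristic(m) == brute_force_euler(m)

    def test_spherical_predicate(self, ball_mask, torus_mask):
        assert is_spherical(ball_mask)
        assert not is_spherical(torus_mask)
        hollow = ball_mask.mask.copy()
        hollow[10, 10, 10] = False  # interior cavity: background disconnected
        assert not is_spherical(hollow)


class TestMargins:
    def test_boundary_voxels_have_zero_margin(self, ball_mask):
        mf = compute_margins(ball_mask)
        b = boundary_voxels(ball_mask.mask)
        assert np.all(mf.margins[b] == 0.0)

    def test_six_adjacent_to_boundary_has_margin_one(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        mf = compute_margins(m)
        # (3,4,4) is 6-adjacent to the boundary voxel (2,4,4) and no closer one
        assert mf.margins[3, 4, 4] == 1.0

    def test_matches_all_pairs_scan(self, rng):
        m = rng.random((10, 10, 10)) < 0.5
        if not m.any() or m.all():
            pytest.skip("degenerate draw")
        mf = compute_margins(m)
        b = np.argwhere(boundary_voxels(m))
        grid = np.moveaxis(np.indices(m.shape), 0, -1).reshape(-1, 3)
        d = np.sqrt(((grid[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(1)
        np.testing.assert_allclose(mf.margins.ravel(), d, atol=1e-9)

    def test_single_phase_rejected(self):
        with pytest.raises(SinglePhaseError):
            compute_margins(np.ones((4, 4, 4), bool))


class TestEmbedding:
    def test_sign_constraints_always_hold(self, handle_cell):
        mf = compute_margins(handle_cell)
        emb = solve_embedding(handle_cell, mf)
        v = np.where(handle_cell.mask, 1.0, -1.0)
        assert np.all(v * emb.f >= mf.margins - 1e-12)

    def test_matches_qp_oracle_energy(self, rng):
        from scipy import optimize, sparse
        mask = np.zeros((8, 8, 8), bool)
        g = np.ogrid[0:8, 0:8, 0:8]
        mask |= ((g[0] - 3.5) ** 2 + (g[1] - 3.5) ** 2 + (g[2] - 3.5) ** 2) <= 9
        mf = compute_margins(mask)
        emb = solve_embedding(mask, mf)
        # oracle: box-constrained quadratic programme on the narrow band
        shape = mask.shape
        n = mask.size
        idx = np.arange(n).reshape(shape)
        rows, cols = [], []
        for ax in range(3):
            sa = [slice(None)] * 3
            sb = [slice(None)] * 3
            sa[ax], sb[ax] = slice(None, -1), slice(1, None)
            rows.append(idx[tuple(sa)].ravel())
            cols.append(idx[tuple(sb)].ravel())
        r, c = np.concatenate(rows), np.concatenate(cols)
        ones = np.ones(len(r))
        A = sparse.coo_matrix((np.concatenate([ones, ones]),
                               (np.concatenate([r, c]), np.concatenate([c, r]))),
                              shape=(n, n)).tocsr()
        L = (sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A).tocsr()
        v = np.where(mask, 1.0, -1.0).ravel()
        mg = mf.margins.ravel()
        lo = np.where(v > 0, mg, -np.inf)
        hi = np.where(v > 0, np.inf, -mg)
        free = mf.band.ravel()
        f0 = (v * mg)
        Lff, Lfc = L[free][:, free], L[free][:, ~free]
        fc = f0[~free]
        res = optimize.minimize(
            lambda x: 0.5 * x @ (Lff @ x) + x @ (Lfc @ fc),
            f0[free], jac=lambda x: Lff @ x + Lfc @ fc, method="L-BFGS-B",
            bounds=np.column_stack([lo[free], hi[free]]),
            options=dict(maxiter=2000, ftol=1e-15, gtol=1e-12))
        f_qp = f0.copy()
        f_qp[free] = res.x
        e_jac = embedding_energy(emb.f)
        e_qp = embedding_energy(f_qp.reshape(shape))
        assert abs(e_jac - e_qp) / max(e_qp, 1e-12) < 1e-4

    def test_all_foreground_band_pins_to_lower_bound(self):
        """Foreground box filling the whole grid except one background slab
        far away: inside-band foreground voxels with no background pressure
        sit at their lower bound m."""
        m = np.ones((12, 6, 6), bool)
        m[:2] = False
        mf = compute_margins(m, band_halfwidth=2.0)
        emb = solve_embedding(m, mf, band_halfwidth=2.0)
        deep = m & mf.band & (np.arange(12)[:, None, None] > 6)
        np.testing.assert_allclose(emb.f[deep], mf.margins[deep], atol=1e-4)

    def test_energy_monotone_over_iterations(self, ball_mask):
        mf = compute_margins(ball_mask)
        prev = None
        for iters in (5, 20, 80, 320):
            emb = solve_embedding(ball_mask, mf, tol=0.0, max_iter=iters)
            e = embedding_energy(emb.f)
            if prev is not None:
                assert e <= prev + 1e-9
            prev = e


class TestProtrusions:
    def test_ball_yields_only_benign_residues(self, ball_mask):
        """A genus-zero ball has no ill protrusions: any subtraction residues
        of the dilation step are tiny and merge back without changing χ."""
        emb = solve_embedding(ball_mask)
        pset = detect_protrusions(emb, ball_mask)
        residue = sum(int(p.sum()) for p in pset.protrusions)
        assert residue < 0.10 * ball_mask.mask.sum()
        merged = pset.body.copy()
        for p in pset.protrusions:
            merged |= p
            assert is_spherical(merged)

    def test_partition_identity(self, handle_cell):
        emb = solve_embedding(handle_cell)
        pset = detect_protrusions(emb, handle_cell)
        union = pset.body.copy()
        for p in pset.protrusions:
            union |= p
        np.testing.assert_array_equal(union, handle_cell.mask)
        assert is_spherical(pset.body)

    def test_handle_cell_yields_protrusions(self, handle_cell):
        emb = solve_embedding(handle_cell)
        pset = detect_protrusions(emb, handle_cell)
        assert len(pset.protrusions) >= 1


class TestFixTopology:
    def test_genus_zero_returned_unchanged(self, ball_mask):
        fixed, report = fix_topology(ball_mask)
        np.testing.assert_array_equal(fixed.mask, ball_mask.mask)
        assert report["changed_fraction"] == 0.0

    def test_three_handles_fixed_to_sphere(self):
        vol = make_cell_mask(SyntheticCellSpec(n_handles=3, rng_seed=42))
        assert euler_characteristic(vol) == -2
        fixed, report = fix_topology(vol)
        assert is_spherical(fixed)
        assert np.all(fixed.mask[vol.mask])  # superset
        assert report["chi_before"] == -2 and report["chi_after"] == 1

    def test_idempotent(self):
        vol = make_cell_mask(SyntheticCellSpec(n_handles=1, rng_seed=13))
        once, _ = fix_topology(vol)
        twice, _ = fix_topology(once)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_cavity_is_unfixable(self):
        m = np.zeros((12, 12, 12), bool)
        m[2:10, 2:10, 2:10] = True
        m[5:7, 5:7, 5:7] = False  # internal cavity
        with pytest.raises(UnfixableTopologyError):
            fix_topology(BinaryVolume(m))
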