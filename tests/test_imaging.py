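"""Function-image generation: formula checks, reconstruction, recovery."""

import numpy as np
import pytest

import vent4d as v
from vent4d.core import DisplacementField, HUImage, LungMask, build_partition
from vent4d.imaging import ReconstructionConfig, reconstruct_voxelwise
from vent4d.regional import RegionalEstimate


def _const_pair(h_ex, h_in, n=32):
    sp = np.ones(3)
    ex = HUImage(np.full((n, n, n), float(h_ex)), sp, np.zeros(3))
    inn = HUImage(np.full((n, n, n), float(h_in)), sp, np.zeros(3))
    fld = DisplacementField(np.zeros((n, n, n, 3)), sp, np.zeros(3))
    m = np.zeros((n, n, n), bool)
    m[4:-4, 4:-4, 4:-4] = True
    return ex, inn, fld, LungMask(m, sp, np.zeros(3))


class TestVentHu:
    def test_equal_phases_zero_ventilation(self):
        ex, inn, fld, mask = _const_pair(-800, -800)
        out = v.vent_hu(ex, inn, fld, mask)
        assert np.allclose(out.values[mask.values], 0.0)

    def test_density_change_formula_value(self):
        # air/tissue bookkeeping oracle: V_air = -HU/1000 per unit volume at
        # fixed tissue -> SV = (V_air_in*J - V_air_ex)/V_air_ex with
        # J = rho_ex/rho_in; for HU -800 -> -850: 1000*(-50)/(-800*150)
        ex, inn, fld, mask = _const_pair(-800, -850)
        rho_ex, rho_in = 0.2, 0.15
        J = rho_ex / rho_in
        air_ex, air_in = 0.8, 0.85
        oracle = (J * air_in - air_ex) / air_ex
        out = v.vent_hu(ex, inn, fld, mask)
        assert out.values[16, 16, 16] == pytest.approx(1000 * (-50) / (-800 * 150))
        assert out.values[16, 16, 16] == pytest.approx(oracle, rel=1e-12)
        assert out.values[16, 16, 16] == pytest.approx(0.41667, abs=5e-6)

    def test_less_air_at_inhale_is_negative(self):
        ex, inn, fld, mask = _const_pair(-800, -700)
        out = v.vent_hu(ex, inn, fld, mask)
        assert np.all(out.values[mask.values] < 0)

    def test_excluded_fraction_guard(self):
        ex, inn, fld, mask = _const_pair(-5, -5)  # H_ex >= -10 everywhere
        with pytest.raises(ValueError, match="excluded"):
            v.vent_hu(ex, inn, fld, mask)


def _mask(n=10, pad=1):
    m = np.zeros((n, n, n), bool)
    m[pad:-pad, pad:-pad, pad:-pad] = True
    return LungMask(m, np.ones(3), np.zeros(3))


class TestReconstructVoxelwise:
    def test_single_region_constant_minimizer(self):
        mask = _mask()
        part = build_partition(mask, window=8, stride=8)
        assert len(part) == 1
        cfg = ReconstructionConfig(lam=0.0)
        ests = [RegionalEstimate(part.regions[0].key, 1.3, 0.01, 100)]
        img, diag = reconstruct_voxelwise(ests, part, mask, cfg)
        assert np.allclose(img.values[mask.values], 1.3, atol=1e-8)

    def test_overlapping_constant_recovery_vs_dense_oracle(self):
        # <= 500 unknowns: compare the sparse path against a dense
        # normal-equations solve of the same objective
        mask = _mask(8, 1)  # 216 voxels
        part = build_partition(mask, window=4, stride=2)
        cfg = ReconstructionConfig(lam=1e-3)
        c = 1.2
        ests = [RegionalEstimate(r.key, c, 0.01, r.n_voxels) for r in part.regions]
        img, diag = reconstruct_voxelwise(ests, part, mask, cfg)
        assert np.allclose(img.values[mask.values], c, atol=1e-6)

        # dense oracle
        m = mask.values
        n = int(m.sum())
        col = -np.ones(m.shape, int)
        col[m] = np.arange(n)
        A = np.zeros((len(ests), n))
        for i, r in enumerate(part.regions):
            A[i, col[tuple(r.indices.T)]] = 1.0 / r.n_voxels
        W = np.eye(len(ests))  # equal SEs -> equal (normalized) weights
        pairs = []
        for ax in range(3):
            sa = [slice(None)] * 3
            sb = [slice(None)] * 3
            sa[ax] = slice(None, -1)
            sb[ax] = slice(1, None)
            sel = m[tuple(sa)] & m[tuple(sb)]
            pairs += list(zip(col[tuple(sa)][sel], col[tuple(sb)][sel]))
        D = np.zeros((len(pairs), n))
        for k, (a, b) in enumerate(pairs):
            D[k, a], D[k, b] = 1.0, -1.0
        H = A.T @ W @ A + cfg.lam * (D.T @ D)
        rhs = A.T @ W @ np.full(len(ests), c)
        dense = np.linalg.solve(H, rhs)
        np.testing.assert_allclose(img.values[m], dense, atol=1e-5)

    def test_infeasible_global_constraint_rejected(self):
        mask = _mask()
        part = build_partition(mask, window=8, stride=8)
        cfg = ReconstructionConfig(epsilon=0.05)
        ests = [RegionalEstimate(part.regions[0].key, 1.0, 0.01, 100)]
        # global mean 0.01 < epsilon
        bad_total = 0.01 * mask.volume_mm3
        with pytest.raises(ValueError, match="infeasible"):
            reconstruct_voxelwise(ests, part, mask, cfg, global_value=bad_total)


class TestMethodRecovery:
    def test_identity_scene_recovers_unity(self, identity_phantom):
        ph = identity_phantom
        part = build_partition(ph.mask)
        m = ph.mask.values
        ij = v.vent_ijf(ph.exhale, ph.inhale, ph.field, ph.mask, ph.mask_in, part, seed=1)
        assert np.sqrt(np.mean((ij.values[m] - 1.0) ** 2)) < 0.02
        mc = v.vent_mcvc(ph.exhale, ph.inhale, ph.field, ph.mask, part)
        assert np.sqrt(np.mean((mc.values[m] - 1.0) ** 2)) < 0.02

    def test_affine_recovery_and_global_constraint(self, affine_phantom, affine_partition):
        ph = affine_phantom
        m = ph.mask.values
        J = ph.truth.jacobian
        ij = v.vent_ijf(
            ph.exhale, ph.inhale, ph.field, ph.mask, ph.mask_in, affine_partition, seed=2
        )
        rmse = np.sqrt(np.mean((ij.values[m] - J[m]) ** 2)) / np.mean(J[m])
        assert rmse <= 0.02
        total = np.nansum(ij.values[m]) * ph.mask.voxel_volume
        assert abs(total - ph.mask_in.volume_mm3) / ph.mask_in.volume_mm3 < 1e-6
        assert np.all(ij.values[m] >= ReconstructionConfig().epsilon * (1 - 1e-9))

        mc = v.vent_mcvc(ph.exhale, ph.inhale, ph.field, ph.mask, affine_partition)
        rmse = np.sqrt(np.mean((mc.values[m] - J[m]) ** 2)) / np.mean(J[m])
        assert rmse <= 0.02

    def test_region_order_invariance(self, affine_phantom, affine_partition):
        import copy

        ph = affine_phantom
        shuffled = copy.copy(affine_partition)
        rng = np.random.default_rng(0)
        shuffled.regions = [
            affine_partition.regions[i]
            for i in rng.permutation(len(affine_partition))
        ]
        a = v.vent_ijf(ph.exhale, ph.inhale, ph.field, ph.mask, ph.mask_in,
                       affine_partition, seed=9)
        b = v.vent_ijf(ph.exhale, ph.inhale, ph.field, ph.mask, ph.mask_in,
                       shuffled, seed=9)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8, equal_nan=True)

    def test_noise_degrades_hu_more_than_mcvc(self):
        # the uncertainty-controlled method should resist HU noise better
        # than the voxelwise density-change formula (directional, 10 seeds)
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ph = v.make_phantom(shape=(32, 32, 32), noise_sd_hu=20.0, seed=seed)
            part = build_partition(ph.mask)
            m = ph.mask.values
            J = ph.truth.jacobian
            hu = v.vent_hu(ph.exhale, ph.inhale, ph.field, ph.mask)
            d = hu.defined_mask & m
            sv = ph.truth.sv_air
            rmse_hu = np.sqrt(np.nanmean((hu.values[d] - sv[d]) ** 2)) / abs(
                np.nanmean(sv[d])
            )
            mc = v.vent_mcvc(ph.exhale, ph.inhale, ph.field, ph.mask, part)
            rmse_mc = np.sqrt(np.mean((mc.values[m] - J[m]) ** 2)) / np.mean(J[m])
            wins += rmse_hu > rmse_mc
        assert wins == n_seeds


class TestPerfImage:
    def test_conserving_scene_near_zero(self, affine_phantom, affine_partition):
        ph = affine_phantom
        out = v.perf_image(ph.exhale, ph.inhale, ph.field, ph.mask, affine_partition)
        vals = out.values[ph.mask.values]
        assert np.all(vals >= 0)
        assert np.mean(vals) <= 0.02

    def test_implant_contrast(self):
        center = np.full(3, 31.0)
        ph = v.make_phantom(
            shape=(32, 32, 32),
            noise_sd_hu=0.0,
            seed=2,
            perfusion=v.PerfusionSpec(center=center, radius_mm=12.0, delta=0.05),
        )
        part = build_partition(ph.mask)
        out = v.perf_image(ph.exhale, ph.inhale, ph.field, ph.mask, part)
        m = ph.mask.values
        imp = ph.truth.mass_change > 0
        inside = np.nanmean(out.values[imp & m])
        outside = np.nanmean(out.values[m & ~imp])
        assert inside > 3 * outside
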