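"""Optical-flow estimator: SSD, Gauss-Newton, global/local stages,
temporal integration — each against independent oracles where possible."""

import numpy as np
import pytest
from scipy import ndimage

from tagflow3d.core import VolumeSequence, DisplacementField
from tagflow3d.ofm import (OFMConfig, GlobalTransform, ssd, gauss_newton_step,
                           estimate_global, estimate_local, estimate_flow,
                           track_sequence, estimate_flow_2d)
from tagflow3d.phantom import warp_volume, synth_displacement, DeformationModel


def naive_ssd(La, Lb, u_vec):
    """Brute-force elementwise oracle for a uniform integer translation."""
    total = 0.0
    nx, ny, nz = La.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                si, sj, sk = i - u_vec[0], j - u_vec[1], k - u_vec[2]
                if 0 <= si < nx and 0 <= sj < ny and 0 <= sk < nz:
                    total += (Lb[i, j, k] - La[si, sj, sk]) ** 2
    return total


class TestSSD:
    def test_identical_pair_zero(self, textured_volume):
        assert ssd(textured_volume, textured_volume, np.zeros(3)) == 0.0

    def test_integer_shift_zero_on_overlap(self, textured_volume):
        t = np.array([2.0, -1.0, 1.0])
        shifted = warp_volume(textured_volume,
                              np.broadcast_to(t, textured_volume.shape + (3,)).copy())
        assert ssd(textured_volume, shifted, t) == pytest.approx(0.0, abs=1e-18)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(7)
        La = rng.random((8, 8, 8))
        Lb = rng.random((8, 8, 8))
        for u in ([0, 0, 0], [1, 0, 0], [2, -1, 1]):
            expected = naive_ssd(La, Lb, u)
            got = ssd(La, Lb, np.asarray(u, dtype=float))
            assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_region_rejected(self, textured_volume):
        with pytest.raises(ValueError, match="region"):
            ssd(textured_volume, textured_volume, np.zeros(3),
                region=np.zeros(textured_volume.shape, dtype=bool))


class TestGaussNewtonStep:
    @staticmethod
    def _quadratic_pair(offset):
        n = 33
        c = (n - 1) / 2.0
        x = np.arange(n, dtype=float)
        qx = (x - c) ** 2 / n
        vol = qx[:, None, None] + qx[None, :, None] * 0.5 + qx[None, None, :] * 0.25
        shifted = qx_shift = ((x - offset - c) ** 2) / n
        volB = qx_shift[:, None, None] + qx[None, :, None] * 0.5 \
            + qx[None, None, :] * 0.25
        return vol, volB

    def test_zero_increment_at_optimum(self, textured_volume):
        t = np.array([1.0, 0.0, -1.0])
        shifted = warp_volume(textured_volume,
                              np.broadcast_to(t, textured_volume.shape + (3,)).copy())
        interior = np.zeros(textured_volume.shape, dtype=bool)
        interior[3:-3, 3:-3, 3:-3] = True
        du = gauss_newton_step(textured_volume, shifted, t, region=interior)
        assert np.linalg.norm(du) < 1e-6

    def test_one_step_recovers_quadratic_offset(self):
        La, Lb = self._quadratic_pair(0.3)
        region = np.zeros(La.shape, dtype=bool)
        region[2:-2, 2:-2, 2:-2] = True
        du = gauss_newton_step(La, Lb, np.zeros(3), region=region)
        assert du[0] == pytest.approx(0.3, abs=1e-3)
        assert abs(du[1]) < 1e-6 and abs(du[2]) < 1e-6

    def test_accepted_step_never_increases_ssd(self, textured_volume):
        rng = np.random.default_rng(3)
        noisy = textured_volume + 0.05 * rng.standard_normal(textured_volume.shape)
        u = np.array([0.4, -0.2, 0.1])
        s0 = ssd(textured_volume, noisy, u)
        du = gauss_newton_step(textured_volume, noisy, u)
        assert ssd(textured_volume, noisy, u + du) <= s0 + 1e-12


class TestEstimateGlobal:
    def test_identity_for_identical_pair(self, textured_volume):
        g = estimate_global(textured_volume, textured_volume)
        assert np.linalg.norm(np.r_[g.translation, g.rotation]) < 1e-3

    def test_translation_recovery(self, small_phantom):
        # the realistic input: a tagged volume, whose oblique tag family
        # provides the through-plane landmarks the estimator relies on
        vol = small_phantom[0].phase(0)
        t = np.array([1.5, -2.0, 0.5])
        moved = warp_volume(vol, np.broadcast_to(t, vol.shape + (3,)).copy())
        g = estimate_global(vol, moved)
        assert np.abs(g.translation - t).max() < 0.1

    def test_rotation_recovery(self, textured_volume):
        angle = np.deg2rad(3.0)
        shape = textured_volume.shape
        center = (np.asarray(shape) - 1) / 2.0
        grid = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                           indexing="ij")
        dx = grid[0] - center[0]
        dy = grid[1] - center[1]
        u = np.zeros(shape + (3,))
        u[..., 0] = np.cos(angle) * dx - np.sin(angle) * dy - dx
        u[..., 1] = np.sin(angle) * dx + np.cos(angle) * dy - dy
        moved = warp_volume(textured_volume, u)
        g = estimate_global(textured_volume, moved)
        assert abs(g.rotation[2] - angle) < np.deg2rad(0.2)

    def test_motion_field_matches_parameters(self):
        g = GlobalTransform(np.array([1.0, 2.0, 3.0]),
                            np.array([0.0, 0.0, 0.1]),
                            np.array([4.0, 4.0, 4.0]))
        u = g.motion_field((9, 9, 9))
        assert np.allclose(u[4, 4, 4], [1.0, 2.0, 3.0])
        # a point offset +1 in x rotates about z: du_y = +omega_z
        assert u[5, 4, 4][1] == pytest.approx(2.0 + 0.1)


class TestEstimateLocal:
    def test_identical_pair_near_zero(self, textured_volume):
        f = estimate_local(textured_volume, textured_volume, None)
        mag = np.linalg.norm(f.u, axis=-1)
        assert np.percentile(mag, 99) < 0.05

    def test_uniform_shift_recovery(self, small_phantom):
        seq, _, mask = small_phantom
        vol = seq.phase(0)
        t = np.array([1.0, 0.0, 0.0])
        moved = warp_volume(vol, np.broadcast_to(t, vol.shape + (3,)).copy())
        f = estimate_flow(vol, moved)
        assert abs(np.median(f.u[mask][:, 0]) - 1.0) < 0.1
        assert abs(np.median(f.u[mask][:, 1])) < 0.1
        assert abs(np.median(f.u[mask][:, 2])) < 0.1

    def test_inverse_consistency(self, small_phantom):
        seq, _, mask = small_phantom
        a, b = seq.phase(0), seq.phase(1)
        fwd = estimate_flow(a, b)
        bwd = estimate_flow(b, a)
        med_f = np.median(fwd.u[mask], axis=0)
        med_b = np.median(bwd.u[mask], axis=0)
        assert np.abs(med_f + med_b).max() < 0.1


class TestEstimateFlow:
    def test_known_smooth_field_recovery(self, small_phantom, small_config):
        seq, _, mask = small_phantom
        vol = seq.phase(0)
        model = DeformationModel(torsion_deg=8, radial_contraction=0.08,
                                 longitudinal_shortening_mm=1.5)
        U = synth_displacement(model, small_config.grid_shape, 1.0,
                               small_config.spacing).U
        assert np.abs(U[mask]).max() <= 2.0
        from tagflow3d.phantom import invert_displacement
        moved = warp_volume(vol, invert_displacement(U))
        f = estimate_flow(vol, moved)
        err = (f.u - U)[mask]
        rms = np.sqrt((err ** 2).mean(axis=0))
        assert np.all(rms < 0.7)

    def test_deterministic(self, small_phantom):
        seq, _, _ = small_phantom
        a, b = seq.phase(0), seq.phase(1)
        f1 = estimate_flow(a, b)
        f2 = estimate_flow(a, b)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.valid, f2.valid)

    def test_translation_equivariance(self, small_phantom):
        # shifting both inputs identically leaves relative motion unchanged
        seq, _, mask = small_phantom
        a, b = seq.phase(0), seq.phase(1)
        t = np.array([2.0, 0.0, 0.0])
        tf = np.broadcast_to(t, a.shape + (3,)).copy()
        a2, b2 = warp_volume(a, tf), warp_volume(b, tf)
        f = estimate_flow(a, b)
        f2 = estimate_flow(a2, b2)
        interior = ndimage.binary_erosion(mask, iterations=3)
        shifted_mask = np.roll(interior, 2, axis=0)
        diff = np.median(f2.u[shifted_mask], axis=0) \
            - np.median(f.u[interior], axis=0)
        assert np.abs(diff).max() < 0.05


class TestTrackSequence:
    def test_static_sequence_zero(self, small_base):
        seq, mask = small_base
        fields = track_sequence(seq)
        for U in fields:
            assert np.abs(U.U[mask]).max() < 0.05

    def test_linear_accumulation_of_uniform_steps(self, textured_volume):
        step = np.array([0.5, 0.0, 0.0])
        vols = [textured_volume]
        for p in range(1, 4):
            u = np.broadcast_to(p * step, textured_volume.shape + (3,)).copy()
            vols.append(warp_volume(textured_volume, u))
        seq = VolumeSequence(np.stack(vols, axis=-1), (0.7, 0.7, 1.5))
        fields = track_sequence(seq)
        interior = np.zeros(textured_volume.shape, dtype=bool)
        interior[6:-6, 6:-6, 4:-4] = True
        med = np.median(fields[3].U[interior], axis=0)
        assert abs(med[0] - 1.5) < 0.15
        assert abs(med[1]) < 0.15 and abs(med[2]) < 0.15

    def test_matches_pointwise_trajectory_oracle(self, small_phantom):
        """Vector integration must equal an explicit per-voxel loop."""
        from tagflow3d.ofm import estimate_flow as ef

        seq, _, _ = small_phantom
        sub = VolumeSequence(seq.data[12:28, 12:28, 4:12, :3],
                             seq.spacing, seq.phase_times[:3])
        fields = track_sequence(sub)
        flows = [ef(sub.phase(p), sub.phase(p + 1)) for p in range(2)]

        def sample(f, pos):
            return np.array([ndimage.map_coordinates(
                f[..., a], [[pos[0]], [pos[1]], [pos[2]]], order=1,
                mode="nearest")[0] for a in range(3)])

        rng = np.random.default_rng(0)
        shape = sub.grid_shape
        for _ in range(20):
            idx = tuple(rng.integers(0, s) for s in shape)
            pos = np.array(idx, dtype=float)
            U = np.zeros(3)
            for f in flows:
                U = U + sample(f.u, pos + U)
            assert np.abs(fields[2].U[idx] - U).max() < 1e-6

    def test_single_phase_rejected(self, textured_volume):
        seq = VolumeSequence(textured_volume[..., None], (1, 1, 1))
        with pytest.raises(ValueError, match="phases"):
            track_sequence(seq)


class TestFlow2D:
    def test_static_sequence_zero(self, small_base):
        seq, mask = small_base
        fields = estimate_flow_2d(seq, OFMConfig(mode="2d"))
        assert fields[0].ndim_vec == 2
        for U in fields:
            assert np.abs(U.U[mask]).max() < 0.05

    def test_matches_3d_for_pure_inplane_motion(self, small_config, small_base):
        seq0, mask = small_base
        vol = seq0.phase(0)
        model = DeformationModel(torsion_deg=6, radial_contraction=0.06,
                                 longitudinal_shortening_mm=0.0)
        n_ph = 3
        vols = [vol]
        from tagflow3d.phantom import invert_displacement
        for p in range(1, n_ph):
            U = synth_displacement(model, small_config.grid_shape,
                                   p / (n_ph - 1), small_config.spacing).U
            vols.append(warp_volume(vol, invert_displacement(U)))
        seq = VolumeSequence(np.stack(vols, axis=-1), small_config.spacing)
        f3 = track_sequence(seq)
        f2 = estimate_flow_2d(seq, OFMConfig(mode="2d"))
        interior = ndimage.binary_erosion(mask, iterations=2)
        diff = f2[-1].U[interior] - f3[-1].U[interior][:, :2]
        assert np.abs(np.median(diff, axis=0)).max() < 0.1
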