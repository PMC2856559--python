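"""Phantom generator: geometry, tags, fading, motion, warping, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tagflow3d.core import VolumeSequence
from tagflow3d.phantom import (PhantomConfig, TagSpec, DeformationModel,
                               make_lv_phantom, tag_field, apply_tags,
                               third_tag_normal, default_tag_specs,
                               synth_displacement, invert_displacement,
                               warp_volume, add_noise, make_tagged_sequence)


class TestMakeLvPhantom:
    def test_intensities_and_mask(self, small_config, small_base):
        seq, mask = small_base
        vol = seq.phase(0)
        m0 = small_config.M0
        assert np.all(vol[mask] > 0) and np.all(vol[mask] <= m0)
        cavity = (vol > 0) & ~mask & (vol < 0.2 * m0)
        assert vol[cavity].mean() < 0.2 * vol[mask].mean()

    def test_deterministic_from_seed(self, small_config):
        a, _ = make_lv_phantom(small_config)
        b, _ = make_lv_phantom(small_config)
        assert np.array_equal(a.data, b.data)

    def test_mask_volume_matches_analytic_annulus(self):
        cfg = PhantomConfig(grid_shape=(64, 64, 64), spacing=(0.7, 0.7, 0.7),
                            wall_extent_mm=30.0)
        _, mask = make_lv_phantom(cfg)
        voxel_vol = np.prod(cfg.spacing)
        analytic = np.pi * (cfg.epi_radius_mm ** 2 - cfg.endo_radius_mm ** 2) \
            * cfg.wall_extent_mm
        assert abs(mask.sum() * voxel_vol - analytic) < 0.10 * analytic

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            PhantomConfig(grid_shape=(16, 16, 16), epi_radius_mm=14.0)


class TestTagField:
    def test_saturation_recovery_and_off_stripe(self):
        spec = TagSpec(normal=(1, 0, 0), spacing=6, width=2)
        shape = (24, 8, 8)
        f0 = tag_field(spec, shape, t_ms=0.0)
        # stripe centre (x = 0 lies on a tag plane) is fully saturated
        assert f0[0, 0, 0] == 0.0
        assert f0[6, 0, 0] == 0.0
        # off-stripe voxels are exactly untouched at any time
        assert f0[3, 0, 0] == 1.0
        f_t1 = tag_field(spec, shape, t_ms=900.0, t1_ms=900.0)
        assert f_t1[0, 0, 0] == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert f_t1[3, 0, 0] == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=2000.0),
           st.floats(min_value=0.0, max_value=2000.0))
    def test_monotone_in_time(self, t1, t2):
        spec = TagSpec(normal=(1, 0, 0), spacing=6, width=2)
        lo, hi = sorted((t1, t2))
        f_lo = tag_field(spec, (12, 4, 4), lo)
        f_hi = tag_field(spec, (12, 4, 4), hi)
        assert np.all(f_hi >= f_lo - 1e-12)
        assert np.all(f_lo >= 0) and np.all(f_lo <= 1)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            TagSpec(normal=(1, 0, 0), spacing=4, width=4)


class TestThirdTagNormal:
    @pytest.mark.parametrize("beta, expected", [
        (90.0, (0.0, 0.0, 1.0)),
        (0.0, (np.sqrt(2) / 2, np.sqrt(2) / 2, 0.0)),
    ])
    def test_limits(self, beta, expected):
        assert third_tag_normal(beta) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("beta", [0, 15, 30, 45, 60, 75, 90])
    def test_unit_norm(self, beta):
        assert np.linalg.norm(third_tag_normal(beta)) == pytest.approx(1.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            third_tag_normal(120.0)


class TestApplyTags:
    def test_no_specs_is_identity(self, small_base):
        seq, _ = small_base
        out = apply_tags(seq, [])
        assert np.array_equal(out.data, seq.data)

    def test_zero_time_stripe_is_black(self, small_base):
        seq, _ = small_base
        seq0 = VolumeSequence(seq.data[..., :1], seq.spacing, [0.0])
        out = apply_tags(seq0, [TagSpec(normal=(1, 0, 0), spacing=6, width=2)])
        # x = 0 plane is a tag plane: fully saturated at t = 0
        assert np.all(out.data[0, :, :, 0] == 0.0)

    def test_output_never_exceeds_base(self, small_base):
        seq, _ = small_base
        out = apply_tags(seq, default_tag_specs())
        assert np.all(out.data <= seq.data + 1e-12)

    def test_tag_contrast_fades_with_time(self, small_base):
        seq, mask = small_base
        times = [100.0, 300.0]
        seq2 = VolumeSequence(seq.data[..., :2], seq.spacing, times)
        out = apply_tags(seq2, default_tag_specs())
        # contrast = drop of masked voxels relative to the untagged base
        drop = [(seq2.data[..., p] - out.data[..., p])[mask].mean()
                for p in range(2)]
        assert drop[1] < drop[0]


class TestSynthDisplacement:
    def test_zero_fraction_is_zero_field(self, small_config):
        U = synth_displacement(DeformationModel(), small_config.grid_shape,
                               0.0, small_config.spacing)
        assert np.all(U.U == 0)

    def test_pure_longitudinal_endpoints(self, small_config):
        model = DeformationModel(torsion_deg=0, radial_contraction=0,
                                 longitudinal_shortening_mm=3.0)
        U = synth_displacement(model, small_config.grid_shape, 1.0,
                               small_config.spacing)
        sz = small_config.spacing[2]
        assert np.allclose(U.U[..., 0, 2], 0.0)                 # apex fixed
        assert np.allclose(U.U[..., -1, 2], -3.0 / sz)          # base shifts
        assert np.allclose(U.U[..., :2], 0.0)

    def test_pure_torsion_wringing(self, small_config):
        model = DeformationModel(torsion_deg=10, radial_contraction=0,
                                 longitudinal_shortening_mm=0)
        U = synth_displacement(model, small_config.grid_shape, 1.0,
                               small_config.spacing)
        assert np.allclose(U.U[..., 2], 0.0)
        nx, ny, nz = small_config.grid_shape
        # rotation angle at base is the negative of the angle at the apex
        ix, iy = nx - 5, (ny - 1) // 2
        dx = ix - (nx - 1) / 2.0
        dy = iy - (ny - 1) / 2.0
        ub = U.U[ix, iy, -1, :2]
        ua = U.U[ix, iy, 0, :2]
        ang_b = np.arctan2(dy + ub[1], dx + ub[0]) - np.arctan2(dy, dx)
        ang_a = np.arctan2(dy + ua[1], dx + ua[0]) - np.arctan2(dy, dx)
        assert ang_b == pytest.approx(-ang_a, rel=1e-6)
        assert abs(ang_b) > 0.01

    @pytest.mark.parametrize("lam", [0.25, 0.5, 0.75])
    def test_linear_in_phase_fraction(self, small_config, lam):
        model = DeformationModel()
        U1 = synth_displacement(model, small_config.grid_shape, 1.0,
                                small_config.spacing)
        Ul = synth_displacement(model, small_config.grid_shape, lam,
                                small_config.spacing)
        assert np.allclose(Ul.U, lam * U1.U, atol=1e-9)


class TestWarpVolume:
    def test_zero_displacement_identity(self, textured_volume):
        u = np.zeros(textured_volume.shape + (3,))
        assert np.array_equal(warp_volume(textured_volume, u), textured_volume)

    def test_integer_shift_is_exact(self, textured_volume):
        shift = np.array([2.0, -1.0, 1.0])
        u = np.broadcast_to(shift, textured_volume.shape + (3,)).copy()
        out = warp_volume(textured_volume, u)
        a = out[2:, :-1, 1:]
        b = textured_volume[:-2, 1:, :-1]
        assert np.allclose(a, b, atol=1e-12)

    def test_smooth_round_trip(self, small_config):
        # warp fidelity is an interpolation property, so measure it on a
        # well band-limited volume (stronger acquisition blur)
        from dataclasses import replace
        cfg = replace(small_config, psf_sigma_vox=1.0)
        vol = make_lv_phantom(cfg)[0].phase(0)
        model = DeformationModel(torsion_deg=2, radial_contraction=0.02,
                                 longitudinal_shortening_mm=0.75)
        U = synth_displacement(model, cfg.grid_shape, 1.0, cfg.spacing).U
        assert np.abs(U).max() <= 1.0
        fwd = warp_volume(vol, U)
        back = warp_volume(fwd, -U)
        interior = (slice(2, -2),) * 3
        err = np.abs(back[interior] - vol[interior]).mean()
        assert err < 0.02 * cfg.M0

    def test_shape_mismatch_rejected(self, textured_volume):
        with pytest.raises(ValueError):
            warp_volume(textured_volume, np.zeros((4, 4, 4, 3)))


class TestInvertDisplacement:
    def test_inverse_composes_to_identity(self, small_config):
        U = synth_displacement(DeformationModel(), small_config.grid_shape,
                               1.0, small_config.spacing).U
        v = invert_displacement(U)
        # v(r) must equal U evaluated at r - v(r)
        from scipy import ndimage
        grid = np.meshgrid(*(np.arange(n, dtype=float) for n in U.shape[:-1]),
                           indexing="ij")
        coords = [g - v[..., a] for a, g in enumerate(grid)]
        U_at = np.stack([ndimage.map_coordinates(U[..., a], coords, order=1,
                                                 mode="nearest")
                         for a in range(3)], axis=-1)
        interior = (slice(2, -2),) * 3
        assert np.abs((v - U_at)[interior]).max() < 1e-3


class TestAddNoise:
    def test_zero_percent_unchanged(self, textured_volume):
        assert np.array_equal(add_noise(textured_volume, 0, 1), textured_volume)

    def test_noise_level_calibrated(self):
        rng = np.random.default_rng(0)
        vol = rng.random((50, 50, 50))
        noisy = add_noise(vol, 20, seed=5)
        sd = (noisy - vol).std()
        expected = 0.20 * vol.max()
        assert abs(sd - expected) < 0.02 * expected

    def test_seed_reproducible(self, textured_volume):
        a = add_noise(textured_volume, 10, seed=9)
        b = add_noise(textured_volume, 10, seed=9)
        assert np.array_equal(a, b)


class TestMakeTaggedSequence:
    def test_truth_exported_per_phase(self, small_phantom, small_config):
        seq, truth, mask = small_phantom
        assert len(truth) == small_config.n_phases
        assert np.all(truth[0].U == 0)
        peak = np.abs(truth[-1].U[mask]).max(axis=0)
        assert peak.max() > 0.5  # the phantom actually moves
        assert mask.any()

    def test_reference_phase_matches_static_tagged_base(self, small_config):
        seq, truth, mask = make_tagged_sequence(
            small_config, motion=DeformationModel(0, 0, 0))
        # no motion: every phase is the tagged base at its own fading time
        base, _ = make_lv_phantom(small_config)
        tagged = apply_tags(base, default_tag_specs(), edge_sigma=0.5)
        assert np.allclose(seq.data, tagged.data, atol=1e-12)
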