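"""Spatiotemporal SVD clutter filter, adaptive cutoff, noise equalization,
and power imaging."""

import numpy as np
import pytest

from camulm.config import SceneConfig
from camulm.iq import IQEnsemble
from camulm.scene import synthesize_noise_reference
from camulm.svdfilter import (NoiseProfile, adaptive_cutoff, apply_noise_equalization,
                              estimate_noise_profile, power_doppler, svd_clutter_filter)


def make_iq(data, **kw):
    meta = dict(pitch_axial_um=38.5, pitch_lateral_um=38.5,
                frame_rate_hz=1000.0, center_freq_mhz=20.0)
    meta.update(kw)
    return IQEnsemble(np.asarray(data, dtype=complex), **meta)


class TestSvdFilter:
    def test_rank1_stack_annihilated_exactly_at_cutoff_1(self):
        rng = np.random.default_rng(0)
        spatial = rng.standard_normal((8, 9))
        temporal = rng.standard_normal(20)
        stack = temporal[:, None, None] * spatial[None]
        out, _ = svd_clutter_filter(make_iq(stack), cutoff=1)
        assert np.sum(np.abs(out.data) ** 2) < 1e-18 * np.sum(np.abs(stack) ** 2)

    def test_cutoff_zero_is_identity(self):
        rng = np.random.default_rng(1)
        stack = rng.standard_normal((10, 6, 7)) + 1j * rng.standard_normal((10, 6, 7))
        out, spec = svd_clutter_filter(make_iq(stack), cutoff=0)
        np.testing.assert_array_equal(out.data, stack)
        assert spec.cutoff == 0

    def test_energy_partition_frobenius_identity(self, rank3_scene):
        _, scene = rank3_scene
        out, spec = svd_clutter_filter(scene.iq, cutoff=3)
        total = np.sum(np.abs(scene.iq.data) ** 2)
        retained = np.sum(np.abs(out.data) ** 2)
        removed = np.sum(spec.values[:3] ** 2)
        assert abs((retained + removed) - total) / total < 1e-6

    def test_bubble_recovery_on_rank3_clutter(self, rank3_scene):
        _, scene = rank3_scene
        out, _ = svd_clutter_filter(scene.iq, cutoff=3)
        b, f = scene.bubbles_only.data.ravel(), out.data.ravel()
        r = np.abs(np.vdot(b, f)) / (np.linalg.norm(b) * np.linalg.norm(f))
        assert r >= 0.9

    def test_clutter_suppression_at_least_20_db(self, rank3_scene):
        cfg, scene = rank3_scene
        out, _ = svd_clutter_filter(scene.iq, cutoff=3)
        mb_power = np.mean(np.abs(scene.bubbles_only.data) ** 2)
        before = np.mean(np.abs(scene.clutter_only.data) ** 2) / mb_power
        residual = out.data - scene.bubbles_only.data
        after = np.mean(np.abs(residual) ** 2) / mb_power
        assert 10 * np.log10(before / after) >= 20.0

    def test_repeated_filtering_composes_by_cutoff_addition(self):
        # zeroing the k leading components of an already-filtered stack
        # removes the next k components: two passes at cutoff k equal one
        # pass at cutoff 2k (the subspace structure is preserved exactly)
        rng = np.random.default_rng(6)
        stack = rng.standard_normal((24, 8, 9)) + 1j * rng.standard_normal((24, 8, 9))
        iq = make_iq(stack)
        once, _ = svd_clutter_filter(iq, cutoff=3)
        twice, _ = svd_clutter_filter(once, cutoff=3)
        direct, _ = svd_clutter_filter(iq, cutoff=6)
        scale = np.abs(stack).max()
        np.testing.assert_allclose(twice.data, direct.data, atol=1e-9 * scale)

    def test_cutoff_out_of_range_rejected(self):
        stack = np.ones((4, 3, 3), dtype=complex)
        with pytest.raises(ValueError):
            svd_clutter_filter(make_iq(stack), cutoff=4)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            svd_clutter_filter(make_iq(np.ones((1, 3, 3))), cutoff=1)


class TestAdaptiveCutoff:
    def test_knee_of_cliff_spectrum(self):
        # brute-force curvature oracle over all interior indices
        sv = np.array([1e6, 1e5, 10, 9.9, 9.8, 9.7, 9.6])
        logs = np.log10(sv)
        curvatures = [logs[i - 1] - 2 * logs[i] + logs[i + 1]
                      for i in range(1, len(sv) - 1)]
        expected = int(np.argmax(curvatures)) + 1
        assert expected == 2
        assert adaptive_cutoff(sv, bounds=(0, 6)) == 2

    def test_flat_spectrum_returns_minimum_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            assert adaptive_cutoff(np.full(10, 3.0), bounds=(2, 8)) == 2

    def test_bounds_clamp(self):
        sv = np.array([1e6, 1e5, 10, 9.9, 9.8])
        assert adaptive_cutoff(sv, bounds=(3, 4)) == 3

    def test_tumor_regime_cutoff_in_10_to_20(self, tumor_regime_scene):
        _, scene = tumor_regime_scene
        _, spec = svd_clutter_filter(scene.iq, cutoff="adaptive")
        assert 10 <= spec.cutoff <= 20


class TestNoiseEqualization:
    def test_white_noise_profile_uniform_within_5_percent(self):
        rng = np.random.default_rng(7)
        stack = (rng.standard_normal((1600, 12, 10))
                 + 1j * rng.standard_normal((1600, 12, 10))) / np.sqrt(2)
        prof = estimate_noise_profile(make_iq(stack), cutoff=0)
        assert prof.gain.std() / prof.gain.mean() < 0.05
        np.testing.assert_allclose(prof.gain.mean(), 1.0, rtol=0.05)

    def test_depth_law_gain_matches_analytic_form(self):
        cfg = SceneConfig(field_depth_mm=2.0, field_width_mm=1.0, n_frames=400,
                          clutter_rank=0, n_bubbles=0, noise_sigma=0.05,
                          noise_depth_tau_mm=0.8, seed=9)
        ref = synthesize_noise_reference(cfg)
        prof = estimate_noise_profile(ref, cutoff=0)
        z = np.arange(ref.n_axial) * cfg.pitch_axial_um / 1000.0
        expected = np.exp(-z / (2 * cfg.noise_depth_tau_mm))
        g = prof.gain[:, 0] / prof.gain[0, 0]
        np.testing.assert_allclose(g, expected / expected[0], rtol=0.12)

    def test_self_normalization_flattens_depth_profile(self):
        cfg = SceneConfig(field_depth_mm=2.0, field_width_mm=1.0, n_frames=400,
                          clutter_rank=0, n_bubbles=0, noise_sigma=0.05,
                          noise_depth_tau_mm=0.8, seed=9)
        ref = synthesize_noise_reference(cfg)
        prof = estimate_noise_profile(ref, cutoff=0)
        eq = apply_noise_equalization(ref, prof)
        row_power = np.mean(np.abs(eq.data) ** 2, axis=(0, 2))
        z = np.arange(len(row_power))
        slope = np.polyfit(z, row_power, 1)[0]
        assert abs(slope * len(row_power)) < 0.1 * row_power.mean()

    def test_unit_profile_is_identity_and_scaling_is_quadratic(self):
        rng = np.random.default_rng(3)
        stack = rng.standard_normal((5, 4, 4)) + 1j * rng.standard_normal((5, 4, 4))
        iq = make_iq(stack)
        unit = NoiseProfile(gain=np.ones((4, 4)))
        np.testing.assert_array_equal(apply_noise_equalization(iq, unit).data, stack)
        scaled = NoiseProfile(gain=np.full((4, 4), 3.0))
        out = apply_noise_equalization(iq, scaled)
        np.testing.assert_allclose(np.sum(np.abs(out.data) ** 2),
                                   9.0 * np.sum(np.abs(stack) ** 2))

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            NoiseProfile(gain=np.zeros((3, 3)))

    def test_geometry_mismatch_rejected(self):
        a = make_iq(np.ones((4, 3, 3)))
        b = make_iq(np.ones((4, 5, 5)))
        with pytest.raises(ValueError):
            estimate_noise_profile(a, b, cutoff=0)


class TestPowerDoppler:
    def test_zero_stack_gives_zero_raster(self):
        assert np.all(power_doppler(make_iq(np.zeros((3, 4, 4)))) == 0)

    def test_static_bubble_argmax_at_bubble_pixel(self):
        stack = np.zeros((6, 8, 8), dtype=complex)
        stack[:, 2, 5] = 1.0
        pw = power_doppler(make_iq(stack))
        assert np.unravel_index(np.argmax(pw), pw.shape) == (2, 5)

    def test_additivity_in_frame_count(self):
        rng = np.random.default_rng(4)
        frame = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        single = power_doppler(make_iq(np.tile(frame, (5, 1, 1))))
        double = power_doppler(make_iq(np.tile(frame, (10, 1, 1))))
        np.testing.assert_allclose(double, 2.0 * single)
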