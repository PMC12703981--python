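"""Phase matching, masking, unwrapping, field conversion and noise weights."""

import numpy as np
import pytest

from ferromap.grids import AcquisitionParams, ComplexVolume, FieldMap, Mask, PhaseVolume, Volume
from ferromap.phantom import wrap_phase
from ferromap.phase_recon import (
    brain_mask,
    estimate_weight_map,
    phase_match_average,
    phase_to_field,
    unwrap_phase,
)


def _ball_mask(n, frac=0.45):
    c = (n - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij", sparse=True)
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= (frac * n) ** 2


class TestPhaseMatchAverage:
    def test_identical_averages_identity(self, rng):
        a = ComplexVolume(data=rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8)))
        m = Mask(data=np.ones((8, 8, 8), bool))
        out = phase_match_average(a, ComplexVolume(data=a.data.copy()), m)
        np.testing.assert_allclose(out.data, a.data, atol=1e-12)

    def test_global_offset_removed_before_averaging(self, rng):
        a = ComplexVolume(data=rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8)))
        b = ComplexVolume(data=a.data * np.exp(1j * np.pi / 2))
        m = Mask(data=np.ones((8, 8, 8), bool))
        out = phase_match_average(a, b, m)
        np.testing.assert_allclose(np.abs(out.data), np.abs(a.data), atol=1e-10)

    def test_empty_mask_errors(self, rng):
        a = ComplexVolume(data=np.ones((4, 4, 4), complex))
        with pytest.raises(ValueError, match="mask"):
            phase_match_average(a, a, Mask(data=np.zeros((4, 4, 4), bool)))

    def test_phase_noise_reduced_by_sqrt2(self, rng):
        n = 22  # > 10^4 voxels
        true = np.exp(1j * 0.3) * np.ones((n, n, n))
        sd = 0.1
        n1 = sd * (rng.standard_normal((n,) * 3) + 1j * rng.standard_normal((n,) * 3))
        n2 = sd * (rng.standard_normal((n,) * 3) + 1j * rng.standard_normal((n,) * 3))
        m = Mask(data=np.ones((n,) * 3, bool))
        out = phase_match_average(ComplexVolume(data=true + n1), ComplexVolume(data=true + n2), m)
        single_sd = np.angle(true * np.exp(-1j * 0.3) + n1 * np.exp(-1j * 0.3)).std()
        avg_sd = np.angle(out.data * np.exp(-1j * 0.3)).std()
        assert single_sd / avg_sd == pytest.approx(np.sqrt(2), rel=0.10)


class TestBrainMask:
    def test_phantom_magnitude_recovers_exact_mask(self):
        m = _ball_mask(32)
        out = brain_mask(Volume(data=m.astype(float)), 0.4)
        assert np.array_equal(out.data, m)

    def test_largest_component_survives(self):
        mag = np.zeros((32, 32, 32))
        mag[4:20, 4:20, 4:20] = 1.0  # large blob
        mag[26:30, 26:30, 26:30] = 1.0  # small blob
        out = brain_mask(Volume(data=mag), 0.4)
        assert out.data[10, 10, 10] and not out.data[28, 28, 28]

    def test_noisy_magnitude_dice_above_099(self, rng):
        m = _ball_mask(48)
        mag = m.astype(float) + rng.normal(0, 0.05, m.shape)
        out = brain_mask(Volume(data=mag), 0.4)
        dice = 2 * (out.data & m).sum() / (out.data.sum() + m.sum())
        assert dice >= 0.99

    def test_zero_magnitude_errors(self):
        with pytest.raises(ValueError):
            brain_mask(Volume(data=np.zeros((8, 8, 8))), 0.4)


class TestUnwrapPhase:
    def test_constant_phase_unchanged(self):
        m = np.ones((6, 6, 6), bool)
        p = PhaseVolume(data=np.full((6, 6, 6), 0.3))
        out = unwrap_phase(p, Volume(data=np.ones((6, 6, 6))), Mask(data=m))
        np.testing.assert_allclose(out.data, 0.3, atol=1e-12)

    def test_wrapped_ramp_recovered(self):
        # 1-D ramp 0 -> 6*pi over 100 voxels, embedded in a thin 3-D slab
        ramp = np.linspace(0, 6 * np.pi, 100)
        true = np.tile(ramp[:, None, None], (1, 3, 3))
        wrapped = wrap_phase(true)
        out = unwrap_phase(
            PhaseVolume(data=wrapped), Volume(data=np.ones_like(true)), Mask(data=np.ones(true.shape, bool))
        )
        d = out.data - true
        k = np.round(np.median(d) / (2 * np.pi))
        assert np.abs(d - 2 * np.pi * k).max() < 1e-9

    def test_output_congruent_to_input_mod_2pi(self, rng):
        n = 16
        m = _ball_mask(n)
        true = rng.normal(0, 2, (n,) * 3)
        from scipy import ndimage

        true = ndimage.gaussian_filter(true, 3) * 10
        wrapped = wrap_phase(true)
        out = unwrap_phase(PhaseVolume(data=wrapped), Volume(data=np.ones((n,) * 3)), Mask(data=m))
        resid = (out.data - wrapped)[m] / (2 * np.pi)
        assert np.abs(resid - np.round(resid)).max() < 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_smooth_field_identity_up_to_global_multiple(self, seed):
        """unwrap(wrap(phi)) == phi + 2*pi*k for smooth fields with in-mask
        gradients below pi per voxel."""
        rng = np.random.default_rng(seed)
        n = 20
        m = _ball_mask(n)
        from scipy import ndimage

        true = ndimage.gaussian_filter(rng.normal(0, 1, (n,) * 3), 2.5)
        true *= 20.0 / max(np.abs(true).max(), 1e-9)
        grad = max(np.abs(np.diff(true, axis=a)).max() for a in range(3))
        if grad >= 2.8:  # keep within the contract's premise (< pi per step)
            true *= 2.8 / grad
        out = unwrap_phase(PhaseVolume(data=wrap_phase(true)), Volume(data=np.ones((n,) * 3)), Mask(data=m))
        d = (out.data - true)[m]
        k = np.round(np.median(d) / (2 * np.pi))
        assert np.abs(d - 2 * np.pi * k).max() < 1e-9

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            unwrap_phase(
                PhaseVolume(data=np.zeros((4, 4, 4))),
                Volume(data=np.ones((4, 4, 4))),
                Mask(data=np.zeros((4, 4, 4), bool)),
            )


class TestPhaseToField:
    def test_zero_phase_zero_field(self, acq):
        out = phase_to_field(PhaseVolume(data=np.zeros((4, 4, 4))), acq)
        assert np.all(out.data == 0)

    def test_known_phase_gives_known_ppm(self):
        acq = AcquisitionParams(te_s=0.019, b0_T=7.0, gamma_bar_MHz_per_T=42.577)
        out = phase_to_field(PhaseVolume(data=np.full((2, 2, 2), 3.558)), acq)
        assert out.data[0, 0, 0] == pytest.approx(0.100, abs=0.001)

    def test_exact_linearity(self, acq, rng):
        phi = rng.standard_normal((6, 6, 6))
        f1 = phase_to_field(PhaseVolume(data=phi), acq).data
        f3 = phase_to_field(PhaseVolume(data=3.0 * phi), acq).data
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-15, atol=0)

    def test_doubling_te_halves_field(self):
        a1 = AcquisitionParams(te_s=0.019)
        a2 = AcquisitionParams(te_s=0.038)
        phi = PhaseVolume(data=np.full((2, 2, 2), 1.0))
        assert phase_to_field(phi, a2).data[0, 0, 0] == pytest.approx(
            phase_to_field(phi, a1).data[0, 0, 0] / 2
        )


class TestEstimateWeightMap:
    def _fields(self, s):
        f1 = FieldMap(data=np.zeros(s.shape))
        f2 = FieldMap(data=np.sqrt(2.0) * s)  # |f1-f2|/sqrt(2) == s exactly
        return f1, f2

    def test_homogeneous_noise_uniform_weights_no_flags(self):
        s = np.full((6, 6, 6), 0.01)
        f1, f2 = self._fields(s)
        w = estimate_weight_map(f1, f2, Mask(data=np.ones(s.shape, bool)))
        np.testing.assert_allclose(w.data, 1.0)
        assert not w.flags.any()

    def test_single_low_sd_voxel_flagged_and_replaced(self):
        # 5-cube toy: one voxel with s 100x smaller than the rest.
        # w there = 100, others = 1; median = 1, IQR = 0 => T = 1, so only
        # the outlier exceeds T; its replacement is the neighborhood mean (1).
        s = np.full((5, 5, 5), 1.0)
        s[2, 2, 2] = 0.01
        f1, f2 = self._fields(s)
        w = estimate_weight_map(f1, f2, Mask(data=np.ones(s.shape, bool)))
        assert w.flags.sum() == 1 and w.flags[2, 2, 2]
        np.testing.assert_allclose(w.data, 1.0)

    def test_max_inmask_weight_is_exactly_one(self, rng):
        s = np.abs(rng.normal(0.01, 0.003, (8, 8, 8))) + 1e-4
        f1, f2 = self._fields(s)
        m = _ball_mask(8, 0.45)
        w = estimate_weight_map(f1, f2, Mask(data=m))
        assert w.data[m].max() == 1.0

    def test_identical_averages_error(self):
        f = FieldMap(data=np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="identical"):
            estimate_weight_map(f, FieldMap(data=f.data.copy()), Mask(data=np.ones((4, 4, 4), bool)))

    def test_weight_monotone_in_sd_for_unflagged(self, rng):
        s = np.abs(rng.normal(0.01, 0.002, (8, 8, 8))) + 5e-3
        f1, f2 = self._fields(s)
        m = np.ones(s.shape, bool)
        w = estimate_weight_map(f1, f2, Mask(data=m))
        ok = ~w.flags & m
        sv, wv = s[ok], w.data[ok]
        order = np.argsort(sv)
        assert np.all(np.diff(wv[order]) <= 1e-12)

    def test_variance_pooling_tames_single_sample_tail(self, rng):
        true_sd = 0.01
        f1 = FieldMap(data=rng.normal(0, true_sd, (16, 16, 16)))
        f2 = FieldMap(data=rng.normal(0, true_sd, (16, 16, 16)))
        m = Mask(data=np.ones((16, 16, 16), bool))
        w_raw = estimate_weight_map(f1, f2, m)
        w_pool = estimate_weight_map(f1, f2, m, pool_radius=1)
        # pooled weights are less dispersed and need far less outlier repair
        assert w_pool.data.std() < 0.8 * w_raw.data.std()
        assert w_pool.flags.sum() < w_raw.flags.sum()
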