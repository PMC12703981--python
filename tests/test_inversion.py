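"""Dipole kernel, forward model, edge mask, MEDI, MERIT and TGV."""

import warnings

import numpy as np
import pytest

from ferromap.grids import AcquisitionParams, FieldMap, Mask, Volume, WeightMap, rad_per_ppm
from ferromap.inversion import (
    InversionConfig,
    crop,
    dipole_kernel,
    edge_mask,
    forward_field,
    medi_invert,
    merit_tune,
    tgv_invert,
    zero_pad,
)
from ferromap.phantom import build_phantom, default_phantom_spec


class TestDipoleKernel:
    def test_on_axis_value(self):
        k = dipole_kernel((16, 16, 16))
        assert k.values[0, 0, 1] == pytest.approx(-2.0 / 3.0)

    def test_transverse_value(self):
        k = dipole_kernel((16, 16, 16))
        assert k.values[1, 0, 0] == pytest.approx(1.0 / 3.0)
        assert k.values[0, 1, 0] == pytest.approx(1.0 / 3.0)

    def test_magic_angle_zero(self):
        # kb^2/|k|^2 = 1/3 at e.g. k = (1, 1, 1) with isotropic voxels
        k = dipole_kernel((16, 16, 16))
        assert k.values[1, 1, 1] == pytest.approx(0.0, abs=1e-15)

    def test_origin_zero_and_bounds(self):
        k = dipole_kernel((12, 10, 8), (1.0, 2.0, 0.5))
        assert k.values[0, 0, 0] == 0.0
        assert k.values.min() >= -2.0 / 3.0 - 1e-12
        assert k.values.max() <= 1.0 / 3.0 + 1e-12

    def test_inversion_symmetry(self):
        k = dipole_kernel((8, 8, 8)).values
        flipped = k[np.ix_(*(np.r_[0, 7:0:-1],) * 3)]
        np.testing.assert_allclose(k, flipped, atol=1e-15)


class TestForwardField:
    def test_uniform_chi_zero_field(self):
        k = dipole_kernel((16,) * 3)
        f = forward_field(np.full((16,) * 3, 0.3), k)
        assert np.abs(f.data).max() < 1e-12

    def test_linearity(self, rng):
        k = dipole_kernel((12,) * 3)
        chi = rng.standard_normal((12,) * 3)
        np.testing.assert_allclose(forward_field(3 * chi, k).data, 3 * forward_field(chi, k).data, atol=1e-12)

    def test_real_chi_real_field(self, rng):
        k = dipole_kernel((12,) * 3)
        f = forward_field(rng.standard_normal((12,) * 3), k).data
        assert np.isrealobj(f)

    def test_uniform_sphere_analytic(self):
        """External on-axis field 2*dchi*a^3/(3 r^3) and zero inside."""
        from ferromap.experiments import sphere_forward_accuracy

        res = sphere_forward_accuracy(n=96, radius=12.0)
        assert res["external_rel_err"] < 0.05
        assert res["internal_max_frac"] < 0.05


class TestEdgeMask:
    def test_exact_penalized_count(self, rng):
        mag = rng.standard_normal((10, 10, 10))
        m = np.ones((10, 10, 10), bool)
        mg = edge_mask(Volume(data=mag), Mask(data=m), 0.95)
        n_entries = int(mg.size)  # all entries are in-mask here
        n_edges = int(np.ceil(0.95 * n_entries))
        assert int((mg == 0).sum()) == n_edges

    def test_scale_invariance(self, rng):
        mag = np.abs(rng.standard_normal((8, 8, 8))) + 0.1
        m = np.ones((8, 8, 8), bool)
        a = edge_mask(Volume(data=mag), Mask(data=m), 0.9)
        b = edge_mask(Volume(data=7.3 * mag), Mask(data=m), 0.9)
        np.testing.assert_array_equal(a, b)

    def test_region_boundaries_are_edges(self):
        spec = default_phantom_spec(n=24, snr=1e12, with_background=False)
        gt = build_phantom(spec)
        mg = edge_mask(Volume(data=gt.magnitude), Mask(data=gt.mask.data), 0.95)
        # boundary entries (magnitude steps between labels) must be exempt
        g = np.abs(np.diff(gt.magnitude, axis=0, append=0))
        boundary = (g > 0.01) & gt.mask.data
        assert np.all(mg[0][boundary] == 0)

    def test_constant_magnitude_warns_all_penalized(self):
        m = np.ones((6, 6, 6), bool)
        with pytest.warns(UserWarning, match="constant magnitude"):
            mg = edge_mask(Volume(data=np.ones((6, 6, 6))), Mask(data=m), 0.95)
        assert np.all(mg[:, m] == 1)


class TestPadCrop:
    def test_pad_shape(self):
        assert zero_pad(np.zeros((64,) * 3), (20, 20, 20)).shape == (104, 104, 104)

    def test_zero_pad_identity(self, rng):
        x = rng.standard_normal((5, 6, 7))
        np.testing.assert_array_equal(zero_pad(x, (0, 0, 0)), x)

    def test_crop_inverts_pad(self, rng):
        x = rng.standard_normal((5, 6, 7))
        np.testing.assert_array_equal(crop(zero_pad(x, (3, 1, 2)), (3, 1, 2)), x)


@pytest.fixture(scope="module")
def phantom32():
    spec = default_phantom_spec(n=32, snr=1e12, with_background=False)
    gt = build_phantom(spec)
    acq = AcquisitionParams()
    kern = dipole_kernel((32,) * 3, acq.voxel_mm)
    f = forward_field(gt.chi_true, kern).data
    m = gt.mask.data
    return {
        "gt": gt,
        "acq": acq,
        "field": FieldMap(data=np.where(m, f, 0.0), voxel_mm=acq.voxel_mm),
        "weights": WeightMap(data=np.where(m, 1.0, 0.0)),
        "mag": Volume(data=gt.magnitude),
    }


def _region_errors(chi, gt, skip_zero=True):
    errs = {}
    for lid, (nm, _, _) in gt.labels.lookup.items():
        sel = gt.labels.data == lid
        t = float(gt.chi_true.data[sel][0])
        if t == 0 and skip_zero:
            continue
        errs[nm] = (float(np.median(chi.data[sel])) - t) / t
    return errs


class TestMedi:
    def test_zero_field_zero_chi(self, phantom32):
        p = phantom32
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=5)
        chi = medi_invert(FieldMap(data=np.zeros((32,) * 3)), p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
        assert np.abs(chi.data).max() < 1e-12

    def test_noiseless_roundtrip_accuracy(self, phantom32):
        p = phantom32
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi = medi_invert(p["field"], p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
        errs = _region_errors(chi, p["gt"])
        assert max(abs(e) for e in errs.values()) < 0.10
        rmse = np.sqrt(np.mean((chi.data - p["gt"].chi_true.data)[p["gt"].mask.data] ** 2))
        assert rmse < 0.02

    def test_objective_nonincreasing(self, phantom32):
        p = phantom32
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi = medi_invert(p["field"], p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
        obj = chi.provenance["objective"]
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(obj, obj[1:]))

    def test_exact_inversion_limit(self, phantom32):
        """With a huge fidelity weight and no noise the solve approaches the
        true solution: region medians within 5%."""
        p = phantom32
        cfg = InversionConfig(lambda_fidelity=1e6, pad_voxels=(8, 8, 8), max_iter=30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi = medi_invert(p["field"], p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
        errs = _region_errors(chi, p["gt"])
        assert max(abs(e) for e in errs.values()) < 0.05

    def test_chi_zero_outside_mask(self, phantom32):
        p = phantom32
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi = medi_invert(p["field"], p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
        assert np.all(chi.data[~p["gt"].mask.data] == 0)


class TestMerit:
    def test_uniform_residuals_no_flags(self, phantom32):
        # zero field: residuals identically zero, nothing exceeds the
        # median-based threshold, weights come back untouched
        p = phantom32
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi, w = merit_tune(
                FieldMap(data=np.zeros((32,) * 3)), p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"]
            )
        assert w.flags.sum() == 0
        np.testing.assert_array_equal(w.data, p["weights"].data)

    def test_corrupted_voxel_flagged_and_improved(self):
        from ferromap.experiments import merit_experiment

        res = merit_experiment(n_seeds=5, seed=123)
        assert res["flagged_fraction"] >= 0.8
        assert res["improved_fraction"] >= 0.8

    def test_round_flag_counts_nonincreasing(self, phantom32, rng):
        p = phantom32
        m = p["gt"].mask.data
        c = rad_per_ppm(p["acq"])
        noisy = p["field"].data + rng.normal(0, 2e-4 / c, p["field"].data.shape)
        fm = FieldMap(data=np.where(m, noisy, 0.0), voxel_mm=p["acq"].voxel_mm)
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi, _ = merit_tune(fm, p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
        counts = chi.provenance["merit_rounds"]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_final_fidelity_not_above_initial(self, phantom32, rng):
        p = phantom32
        m = p["gt"].mask.data
        c = rad_per_ppm(p["acq"])
        noisy = p["field"].data + rng.normal(0, 2e-4 / c, p["field"].data.shape)
        noisy[15, 15, 15] += 30e-4 / c
        fm = FieldMap(data=np.where(m, noisy, 0.0), voxel_mm=p["acq"].voxel_mm)
        cfg = InversionConfig(pad_voxels=(8, 8, 8), max_iter=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi0 = medi_invert(fm, p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"])
            chi, _ = merit_tune(fm, p["weights"], p["mag"], p["gt"].mask, cfg, p["acq"], chi0=chi0)
        assert chi.provenance["merit_fidelity_final"] <= chi.provenance["merit_fidelity_initial"] * (1 + 1e-9)


class TestTgv:
    def test_zero_field_zero_chi(self, phantom32):
        p = phantom32
        chi = tgv_invert(FieldMap(data=np.zeros((32,) * 3)), p["gt"].mask, iterations=50, acq=p["acq"], pad_voxels=(8, 8, 8))
        assert np.abs(chi.data).max() < 1e-10

    def test_noiseless_roundtrip_within_15pct(self, phantom32):
        p = phantom32
        chi = tgv_invert(p["field"], p["gt"].mask, iterations=500, acq=p["acq"], pad_voxels=(8, 8, 8))
        errs = _region_errors(chi, p["gt"])
        assert max(abs(e) for e in errs.values()) < 0.15

    def test_residual_decreases_tenfold(self, phantom32):
        p = phantom32
        chi = tgv_invert(p["field"], p["gt"].mask, iterations=300, acq=p["acq"], pad_voxels=(8, 8, 8))
        res = chi.provenance["residuals"]
        assert res[-1] * 10 <= res[9]

    def test_alphas_validated(self, phantom32):
        p = phantom32
        with pytest.raises(ValueError):
            tgv_invert(p["field"], p["gt"].mask, alphas=(0.0, 1e-4))
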