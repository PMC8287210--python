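import numpy as np
import pytest
from scipy import ndimage

from gratiomap.cov_analysis import (
    cov_bland_altman,
    cov_map,
    tissue_weighted_smooth,
)
from gratiomap.volume_io import VolumeMap


def _vol(values, affine=None):
    return VolumeMap(np.asarray(values, float), affine if affine is not None else np.eye(4))


class TestTissueWeightedSmooth:
    def test_zero_fwhm_identity_on_supported_voxels(self, rng):
        vol = _vol(rng.normal(size=(4, 4, 4)))
        tpm = _vol(rng.uniform(0.2, 1.0, (4, 4, 4)))
        out = tissue_weighted_smooth(vol, tpm, fwhm_mm=0.0, support_cutoff=0.05)
        np.testing.assert_allclose(out.values, vol.values, rtol=1e-12)

    def test_constant_preserved(self, rng):
        vol = _vol(np.full((5, 5, 5), 3.25))
        tpm = _vol(rng.uniform(0.3, 1.0, (5, 5, 5)))
        out = tissue_weighted_smooth(vol, tpm, fwhm_mm=6.0)
        defined = np.isfinite(out.values)
        assert defined.any()
        np.testing.assert_allclose(out.values[defined], 3.25, rtol=1e-12)

    def test_linear_in_map_argument(self, rng):
        a = _vol(rng.normal(size=(5, 5, 5)))
        b = _vol(rng.normal(size=(5, 5, 5)))
        tpm = _vol(rng.uniform(0.3, 1.0, (5, 5, 5)))
        sa = tissue_weighted_smooth(a, tpm, 4.0).values
        sb = tissue_weighted_smooth(b, tpm, 4.0).values
        sab = tissue_weighted_smooth(a.with_values(2 * a.values + b.values), tpm, 4.0).values
        np.testing.assert_allclose(sab, 2 * sa + sb, rtol=1e-10)

    def test_matches_hand_discrete_convolution_1d(self):
        # 3-voxel line with uniform tissue: the ratio reduces to plain
        # Gaussian smoothing, reproduced here against the discrete kernel
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1.0, 2.0, 4.0]
        vol = _vol(vals)
        tpm = _vol(np.ones((3, 1, 1)))
        fwhm = 2.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = tissue_weighted_smooth(vol, tpm, fwhm, support_cutoff=0.0)
        expected = ndimage.gaussian_filter(vals, sigma=[sigma, sigma, sigma], mode="reflect")
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_low_support_becomes_undefined(self):
        vol = _vol(np.ones((3, 3, 3)))
        tpm = _vol(np.zeros((3, 3, 3)))
        out = tissue_weighted_smooth(vol, tpm, 2.0, support_cutoff=0.05)
        assert np.isnan(out.values).all()

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            tissue_weighted_smooth(_vol(np.ones((2, 2, 2))), _vol(np.ones((2, 2, 2))), -1.0)

    def test_fwhm_respects_voxel_size(self, rng):
        # same world-space kernel on a coarser grid = smaller voxel sigma
        vals = rng.normal(size=(9, 9, 9))
        fine = VolumeMap(vals, np.diag([1.0, 1.0, 1.0, 1.0]))
        coarse = VolumeMap(vals, np.diag([3.0, 3.0, 3.0, 1.0]))
        tpm_f = VolumeMap(np.ones((9, 9, 9)), fine.affine)
        tpm_c = VolumeMap(np.ones((9, 9, 9)), coarse.affine)
        sf = tissue_weighted_smooth(fine, tpm_f, 6.0).values
        sc = tissue_weighted_smooth(coarse, tpm_c, 6.0).values
        # coarser grid -> less smoothing in voxel units -> closer to input
        assert np.abs(sc - vals).sum() < np.abs(sf - vals).sum()


class TestCovMap:
    def test_identical_maps_zero(self, rng):
        m = _vol(rng.uniform(0.5, 1.0, (3, 3, 3)))
        cm = cov_map([m, m, m])
        np.testing.assert_allclose(cm.cov.values, 0.0, atol=1e-12)

    def test_hand_value(self):
        vals = [0.9, 1.1, 0.9, 1.1]
        maps = [_vol(np.full((2, 2, 2), v)) for v in vals]
        cm = cov_map(maps)
        expected = 100 * np.std(vals, ddof=1) / np.mean(vals)  # 11.547%
        np.testing.assert_allclose(cm.cov.values, expected, rtol=1e-9)
        assert cm.cov.values[0, 0, 0] == pytest.approx(11.547, abs=5e-4)

    def test_zero_mean_undefined(self):
        maps = [_vol(np.full((2, 2, 2), 1.0)), _vol(np.full((2, 2, 2), -1.0))]
        cm = cov_map(maps)
        assert np.isnan(cm.cov.values).all()

    def test_scale_invariance(self, rng):
        maps = [_vol(rng.uniform(0.5, 1.5, (3, 3, 3))) for _ in range(4)]
        c1 = cov_map(maps).cov.values
        c2 = cov_map([m.with_values(7.3 * m.values) for m in maps]).cov.values
        np.testing.assert_allclose(c1, c2, rtol=1e-10)

    def test_needs_two_maps(self):
        with pytest.raises(ValueError):
            cov_map([_vol(np.ones((2, 2, 2)))])


class TestCovBlandAltman:
    def test_identical_maps_zero(self, rng):
        cm = cov_map([_vol(rng.uniform(0.5, 1.5, (3, 3, 3))) for _ in range(3)])
        res = cov_bland_altman(cm, cm)
        assert res.bias == 0.0
        assert res.error == 0.0

    def test_constant_offset(self, rng):
        cm = cov_map([_vol(rng.uniform(0.5, 1.5, (3, 3, 3))) for _ in range(3)])
        shifted = cov_map([_vol(rng.uniform(0.5, 1.5, (3, 3, 3))) for _ in range(3)])
        shifted.cov.values[:] = cm.cov.values + 2.0
        res = cov_bland_altman(cm, shifted)
        assert res.bias == pytest.approx(-2.0, rel=1e-12)
        assert res.error == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_from_delta_list(self, rng):
        a = cov_map([_vol(rng.uniform(0.5, 1.5, (3, 3, 3))) for _ in range(3)])
        b = cov_map([_vol(rng.uniform(0.5, 1.5, (3, 3, 3))) for _ in range(3)])
        res = cov_bland_altman(a, b)
        deltas = (a.cov.values - b.cov.values).ravel()
        deltas = deltas[np.isfinite(deltas)]
        assert res.bias == pytest.approx(deltas.mean(), rel=1e-12)
        assert res.error == pytest.approx(1.96 * deltas.std(ddof=1), rel=1e-12)
        assert res.relative_bias_pct == pytest.approx(
            100 * deltas.mean() / np.nanmean(a.cov.values), rel=1e-10
        )
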