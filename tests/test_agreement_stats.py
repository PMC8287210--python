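import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gratiomap import reference_tables as ref
from gratiomap.agreement_stats import (
    bland_altman,
    dynamic_range,
    group_roi_means,
    roi_means,
)
from gratiomap.agreement_stats import test_retest as retest
from gratiomap.volume_io import LabelAtlas, VolumeMap


class TestRoiMeans:
    def _atlas(self):
        labels = np.zeros((4, 4, 4), int)
        labels[0] = 1
        labels[1] = 2
        return LabelAtlas(labels, {1: "a", 2: "b"})

    def test_constant_map(self):
        atlas = self._atlas()
        means = roi_means(VolumeMap(np.full((4, 4, 4), 0.7)), atlas, [1, 2])
        assert means.to_numpy() == pytest.approx(0.7)

    def test_two_voxel_mean(self):
        labels = np.zeros((2, 1, 1), int)
        labels[:, 0, 0] = 9
        atlas = LabelAtlas(labels, {9: "x"})
        vals = np.zeros((2, 1, 1))
        vals[:, 0, 0] = [0.6, 0.7]
        assert roi_means(VolumeMap(vals), atlas, [9])[9] == pytest.approx(0.65)

    def test_restriction_mask(self):
        atlas = self._atlas()
        vals = np.zeros((4, 4, 4))
        vals[0] = 1.0
        vals[0, 0] = 5.0
        restrict = np.zeros((4, 4, 4), bool)
        restrict[0, 0] = True
        means = roi_means(VolumeMap(vals), atlas, [1], restrict_mask=restrict)
        assert means[1] == pytest.approx(5.0)

    def test_empty_roi_raises(self):
        atlas = self._atlas()
        with pytest.raises(ValueError, match="empty"):
            roi_means(VolumeMap(np.ones((4, 4, 4))), atlas, [1],
                      restrict_mask=np.zeros((4, 4, 4), bool))

    def test_noiseless_phantom_recovery(self):
        from gratiomap.synthetic_phantom import generate
        from conftest import make_config, noiseless_kwargs

        cfg = make_config(**noiseless_kwargs(b1_amplitude=0.0, un_error_amplitude=0.0))
        ds = generate(cfg)
        means = roi_means(ds.truth["g"], ds.atlas, ds.atlas.ids)
        for spec in cfg.rois:
            expected = np.sqrt(spec.avf_true / (spec.mvf_true + spec.avf_true))
            assert means[spec.roi_id] == pytest.approx(expected, rel=1e-12)


class TestDynamicRange:
    def test_published_roi_means(self):
        # recomputing the summary dynamic ranges from the 21 published
        # per-ROI group means reproduces the published values exactly
        for metric in ("g", "avf", "mvf"):
            dr = dynamic_range(ref.HIGH_SNR_ROI_TABLE[metric])
            assert round(dr, 3) == ref.SUMMARY.loc[metric, "dynamic_range"]

    def test_constant_means(self):
        assert dynamic_range([0.5, 0.5, 0.5]) == 0.0

    def test_needs_two(self):
        with pytest.raises(ValueError):
            dynamic_range([0.5])


class TestBlandAltman:
    def test_identity_exact_zero(self, rng):
        x = rng.normal(size=21)
        res = bland_altman(x, x, dr=1.0)
        assert res.bias == 0.0
        assert res.error == 0.0

    def test_unit_sd_deltas(self):
        # deltas {-1, 0, 1}: sample SD = 1, so error = 1.96 exactly
        res = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.error == pytest.approx(1.96, rel=1e-12)

    def test_published_relative_bias(self):
        # bias -0.041 over dynamic range 0.046 -> -89.13%
        res = bland_altman([0.0, 0.0], [0.041, 0.041], dr=0.046)
        assert round(res.relative_bias_pct, 2) == -89.13

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        fwd = bland_altman(a, b, dr=1.0)
        rev = bland_altman(b, a, dr=1.0)
        np.testing.assert_allclose(rev.delta, -fwd.delta)
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.error == pytest.approx(fwd.error)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_brute_force_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=n), r.normal(size=n)
        res = bland_altman(a, b, dr=2.5)
        deltas = [float(x - y) for x, y in zip(a, b)]
        bias = sum(deltas) / n
        var = sum((d - bias) ** 2 for d in deltas) / (n - 1)
        err = 1.96 * var**0.5
        assert res.bias == pytest.approx(bias, rel=1e-12, abs=1e-15)
        assert res.error == pytest.approx(err, rel=1e-12, abs=1e-15)
        assert res.relative_bias_pct == pytest.approx(100 * bias / 2.5, rel=1e-12, abs=1e-12)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    def test_nonpositive_dr(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.5], dr=0.0)


class TestTestRetest:
    def _series(self, values, ids=(1, 2, 3)):
        return pd.Series(dict(zip(ids, values)))

    def test_identical_sessions_zero(self):
        s = [self._series([0.6, 0.7, 0.65]), self._series([0.62, 0.71, 0.66])]
        res = retest(s, s, dr=0.1)
        assert res.bias == 0.0
        assert res.error == 0.0

    def test_known_shift(self):
        s1 = [self._series([0.60, 0.70, 0.65])]
        s2 = [self._series([0.59, 0.69, 0.64])]
        res = retest(s1, s2, dr=0.1)
        assert res.bias == pytest.approx(0.01, rel=1e-12)
        assert res.error == pytest.approx(0.0, abs=1e-12)
        assert res.relative_bias_pct == pytest.approx(10.0, rel=1e-12)

    def test_session_noise_scale_recovered(self):
        # with pure session noise of SD sigma on each ROI group mean, the
        # expected error is 1.96 * sqrt(2) * sigma; check within Monte-Carlo
        # tolerance by pooling many simulated comparisons
        r = np.random.default_rng(42)
        sigma = 0.01
        n_roi, n_rep = 40, 200
        errs = []
        truth = r.uniform(0.6, 0.7, n_roi)
        for _ in range(n_rep):
            s1 = [pd.Series(truth + r.normal(0, sigma, n_roi))]
            s2 = [pd.Series(truth + r.normal(0, sigma, n_roi))]
            errs.append(retest(s1, s2).error)
        expected = 1.96 * np.sqrt(2) * sigma
        assert np.mean(errs) == pytest.approx(expected, rel=0.05)

    def test_roi_set_mismatch(self):
        s1 = [self._series([0.6, 0.7, 0.65], ids=(1, 2, 3))]
        s2 = [self._series([0.6, 0.7, 0.65], ids=(1, 2, 4))]
        with pytest.raises(ValueError):
            retest(s1, s2)


class TestGroupRoiMeans:
    def test_mean_and_sd(self):
        s1 = pd.Series({1: 0.6, 2: 0.7})
        s2 = pd.Series({1: 0.8, 2: 0.7})
        g = group_roi_means([s1, s2])
        assert g.loc[1, "mean"] == pytest.approx(0.7)
        assert g.loc[1, "sd"] == pytest.approx(np.std([0.6, 0.8], ddof=1))
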