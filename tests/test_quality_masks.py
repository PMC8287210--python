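import numpy as np
import pytest

from gratiomap.quality_masks import (
    SnrMaskConfig,
    group_wm_mask,
    high_snr_mask,
    optimize_snr_threshold,
    select_rois,
    snr_map,
)
from gratiomap.volume_io import LabelAtlas, VolumeMap


def _vol(values):
    return VolumeMap(np.asarray(values, dtype=float))


class TestSnrMap:
    @pytest.mark.parametrize(
        "b0, sigma, n, expected",
        [
            (60.0, 60.0, 1, 1.0),
            (200.0, 60.0, 12, (10.0 / 3.0) * np.sqrt(12)),  # 11.5470...
        ],
    )
    def test_hand_values(self, b0, sigma, n, expected):
        out = snr_map(VolumeMap(np.full((2, 2, 2), b0)), sigma, n)
        assert out.values == pytest.approx(expected, rel=1e-12)

    def test_threshold_boundary_inversion(self):
        b0 = 39 * 60.0 / np.sqrt(12)
        out = snr_map(VolumeMap(np.full((1, 1, 1), b0)), 60.0, 12)
        assert out.values == pytest.approx(39.0, rel=1e-12)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            snr_map(VolumeMap(np.ones((2, 2, 2))), 0.0)


class TestGroupWmMask:
    def test_all_ones_full_mask(self):
        tpms = [VolumeMap(np.ones((3, 3, 3)))] * 3
        assert group_wm_mask(tpms, 0.95).values.sum() == 27

    def test_mean_below_threshold_excluded(self):
        a = VolumeMap(np.full((2, 2, 2), 1.0))
        b = VolumeMap(np.full((2, 2, 2), 0.8))
        mask = group_wm_mask([a, b], 0.95)  # mean 0.9 < 0.95
        assert mask.values.sum() == 0

    def test_strict_threshold(self):
        vals = np.ones((2, 2, 2))
        vals[0, 0, 0] = 0.999
        mask = group_wm_mask([VolumeMap(vals)], 1.0)
        assert mask.values.sum() == 7


class TestThresholdSearch:
    def test_all_clean_ties_break_small(self):
        snr = _vol(np.linspace(1, 50, 64).reshape(4, 4, 4))
        icvf = _vol(np.full((4, 4, 4), 0.5))
        wm = np.ones((4, 4, 4), bool)
        res = optimize_snr_threshold([snr], [icvf], wm, SnrMaskConfig(threshold_grid=(1, 2, 5)))
        assert res.chosen_threshold == 1.0
        assert (res.table["mean_ratio"] == 0).all()

    def test_eight_voxel_enumeration(self):
        # SNR {1,1,2,2,2,3,3,3}; artifact voxels marked at two SNR=1 and one
        # SNR=2 position; hand ratios: t=1 -> 3/8, t=2 -> 1/6, t=3 -> 0/3
        snr = _vol(np.array([1, 1, 2, 2, 2, 3, 3, 3], float).reshape(2, 2, 2))
        icvf_vals = np.full(8, 0.5)
        icvf_vals[[0, 1, 2]] = 0.9995
        icvf = _vol(icvf_vals.reshape(2, 2, 2))
        wm = np.ones((2, 2, 2), bool)
        res = optimize_snr_threshold([snr], [icvf], wm, SnrMaskConfig(threshold_grid=(1, 2, 3)))
        np.testing.assert_allclose(res.table["mean_ratio"], [3 / 8, 1 / 6, 0.0])
        assert res.chosen_threshold == 3.0

    def test_matches_brute_force_enumeration(self, rng):
        # independent oracle: nested-loop recount on random <=10^3-voxel data
        cfg = SnrMaskConfig(threshold_grid=tuple(range(1, 21)), ceiling_cutoff=0.999)
        for _ in range(3):
            shape = (8, 8, 8)
            snr_maps = [_vol(rng.uniform(0, 25, shape)) for _ in range(3)]
            icvf_maps = [_vol(rng.choice([0.5, 0.9999], p=[0.8, 0.2], size=shape)) for _ in range(3)]
            wm = rng.random(shape) > 0.3
            res = optimize_snr_threshold(snr_maps, icvf_maps, wm, cfg)
            # brute force
            best_t, best_mean = None, None
            for t in cfg.threshold_grid:
                ratios = []
                for snr, icvf in zip(snr_maps, icvf_maps):
                    num = den = 0
                    for idx in np.ndindex(shape):
                        if wm[idx] and snr.values[idx] >= t:
                            den += 1
                            if icvf.values[idx] >= 0.999:
                                num += 1
                    if den:
                        ratios.append(num / den)
                if not ratios:
                    continue
                mean = sum(ratios) / len(ratios)
                if best_mean is None or mean < best_mean - 1e-15:
                    best_t, best_mean = t, mean
            assert res.chosen_threshold == best_t
            row = res.table.set_index("threshold").loc[best_t]
            assert row["mean_ratio"] == pytest.approx(best_mean, rel=1e-12)

    def test_raising_cutoff_never_increases_ratio(self, rng):
        shape = (6, 6, 6)
        snr = _vol(rng.uniform(0, 20, shape))
        icvf = _vol(rng.uniform(0.9, 1.0, shape))
        wm = np.ones(shape, bool)
        grid = tuple(range(1, 15))
        lo = optimize_snr_threshold([snr], [icvf], wm,
                                    SnrMaskConfig(threshold_grid=grid, ceiling_cutoff=0.95))
        hi = optimize_snr_threshold([snr], [icvf], wm,
                                    SnrMaskConfig(threshold_grid=grid, ceiling_cutoff=0.999))
        merged = lo.table.merge(hi.table, on="threshold", suffixes=("_lo", "_hi"))
        assert (merged["mean_ratio_hi"] <= merged["mean_ratio_lo"] + 1e-15).all()


class TestSelectRois:
    def _setup(self):
        labels = np.zeros((6, 6, 6), int)
        labels[0:2, 0:2, 0:2] = 1       # fully inside everything
        labels[3:5, 0:5, 0:5] = 2       # partially outside high-SNR
        labels[5, 5, 5] = 3             # one voxel outside WM
        atlas = LabelAtlas(labels, {1: "in", 2: "partial", 3: "out"})
        wm = np.ones((6, 6, 6), bool)
        wm[5, 5, 5] = False
        return atlas, wm

    def test_rules(self):
        atlas, wm = self._setup()
        hs = wm.copy()
        # remove 2 of ROI 2's 50 voxels from the high-SNR mask -> 96% overlap
        hs[3, 0, 0] = False
        hs[3, 0, 1] = False
        whole, high, table = select_rois(atlas, wm, hs, overlap_min=0.95)
        assert whole == [1, 2]
        assert high == [1, 2]
        t = table.set_index("id")
        assert t.loc[2, "overlap_frac"] == pytest.approx(0.96)
        assert not t.loc[3, "in_whole_wm"]

    def test_overlap_below_min_excluded(self):
        atlas, wm = self._setup()
        hs = wm.copy()
        hs[3] = False  # drops half of ROI 2
        whole, high, _ = select_rois(atlas, wm, hs, overlap_min=0.95)
        assert whole == [1, 2]
        assert high == [1]

    def test_high_subset_of_whole(self, rng):
        labels = rng.integers(0, 5, (6, 6, 6))
        atlas = LabelAtlas(labels, {i: f"r{i}" for i in range(1, 5)})
        wm = rng.random((6, 6, 6)) > 0.2
        hs = wm & (rng.random((6, 6, 6)) > 0.3)
        whole, high, _ = select_rois(atlas, wm, hs)
        assert set(high) <= set(whole)

    def test_high_snr_mask_intersection(self):
        wm = VolumeMap(np.ones((2, 2, 2)))
        snr = _vol(np.array([10, 50, 10, 50, 10, 50, 10, 50], float).reshape(2, 2, 2))
        out = high_snr_mask(wm, snr, 39.0)
        assert out.values.sum() == 4
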