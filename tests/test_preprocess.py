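import numpy as np
import pytest

from msunet.preprocess import (AugmentParams, NormalizationError, Patch,
                               augment, extract_training_patches, normalize,
                               plan_patches)
from msunet.volume_io import CHANNEL_ORDER, LesionMask, MultimodalVolume, \
    VolumeGrid

from conftest import make_volume


def brute_force_normalize(x):
    """Independent reference: min-max, percentile clip, z-score over the
    in-band voxels (nonzero voxels only)."""
    brain = x != 0
    v = x[brain]
    v = (v - v.min()) / (v.max() - v.min())
    lo, hi = np.percentile(v, [1, 99])
    in_band = v[(v >= lo) & (v <= hi)]
    clipped = np.clip(v, lo, hi)
    out = np.zeros_like(x, dtype=float)
    out[brain] = (clipped - in_band.mean()) / in_band.std()
    return out


class TestNormalize:
    def test_in_band_voxels_zero_mean_unit_sd(self, trial_grid, rng):
        vol = make_volume(trial_grid, rng)
        out = normalize(vol)
        for name in CHANNEL_ORDER:
            x = out.channels[name]
            brain = vol.channels[name] != 0
            vals = x[brain]
            # nearly all voxels are in-band; mean/sd of the in-band subset
            lo, hi = np.percentile(vals, [1, 99])
            in_band = vals[(vals >= lo) & (vals <= hi)]
            assert abs(in_band.mean()) < 0.05
            assert abs(in_band.std() - 1.0) < 0.05

    def test_constant_channel_raises(self, trial_grid):
        channels = {k: np.full(trial_grid.shape, 7.0, dtype=np.float32)
                    for k in CHANNEL_ORDER}
        vol = MultimodalVolume(trial_grid, channels)
        with pytest.raises(NormalizationError):
            normalize(vol)

    def test_idempotent_up_to_clipping(self, trial_grid, rng):
        """Re-normalising an already-normalised volume changes only the
        clipped percentile tails."""
        vol = make_volume(trial_grid, rng)
        once = normalize(vol)
        twice = normalize(once)
        for name in CHANNEL_ORDER:
            a = once.channels[name]
            b = twice.channels[name]
            brain = vol.channels[name] != 0
            lo, hi = np.percentile(a[brain], [1, 99])
            core = brain & (a >= lo) & (a <= hi)
            np.testing.assert_allclose(b[core], a[core], atol=0.05)

    def test_outlier_clipped_matches_brute_force(self, rng):
        grid = VolumeGrid((10, 10, 10), (1, 1, 1))
        x = 50 + 5 * rng.standard_normal(grid.shape)
        x[3, 3, 3] = 1e6  # single extreme outlier
        vol = MultimodalVolume(grid, {k: x.astype(np.float32)
                                      for k in CHANNEL_ORDER})
        out = normalize(vol)
        ref = brute_force_normalize(x.astype(np.float64))
        np.testing.assert_allclose(out.channels["FLAIR"], ref, atol=1e-4)
        # the outlier is clipped, so its z-score is modest
        assert out.channels["FLAIR"][3, 3, 3] < 10


class TestPlanPatches:
    def test_exact_fit_single_origin(self):
        grid = VolumeGrid((32, 96, 96), (3, 1, 1))
        plan = plan_patches(grid, (32, 96, 96), 0.2)
        assert plan.origins == [(0, 0, 0)]

    def test_1d_analogue_origins(self):
        # length 100, patch 96, overlap 0.2: stride 77, second clamped to 4
        plan = plan_patches((1, 1, 100), (1, 1, 96), 0.2)
        assert [o[2] for o in plan.origins] == [0, 4]
        covered = np.zeros(100, dtype=int)
        for (_, _, x) in plan.origins:
            covered[x:x + 96] += 1
        assert (covered >= 1).all()

    def test_coverage_on_double_grid(self):
        grid = VolumeGrid((64, 192, 192), (3, 1, 1))
        plan = plan_patches(grid, (32, 96, 96), 0.2)
        count = np.zeros(grid.shape, dtype=int)
        for (z, y, x) in plan.origins:
            count[z:z + 32, y:y + 96, x:x + 96] += 1
        assert count.min() >= 1

    def test_coverage_random_combinations(self, rng):
        """Property: the union of planned patches covers the padded grid."""
        for _ in range(200):
            shape = tuple(int(rng.integers(4, 40)) for _ in range(3))
            patch = tuple(int(rng.integers(2, 12)) for _ in range(3))
            overlap = float(rng.uniform(0, 0.8))
            plan = plan_patches(shape, patch, overlap)
            padded = tuple(s + p0 + p1
                           for s, (p0, p1) in zip(shape, plan.padding))
            count = np.zeros(padded, dtype=int)
            for (z, y, x) in plan.origins:
                count[z:z + patch[0], y:y + patch[1], x:x + patch[2]] += 1
            assert count.min() >= 1

    def test_overlap_one_rejected(self):
        with pytest.raises(ValueError):
            plan_patches((10, 10, 10), (5, 5, 5), 1.0)


class TestExtractTrainingPatches:
    def test_single_lesion_single_patch(self, rng):
        grid = VolumeGrid((32, 96, 96), (3, 1, 1))
        m = np.zeros(grid.shape, dtype=np.uint8)
        m[16, 48, 46:51] = 1  # 5-voxel central lesion
        mask = LesionMask(grid, m)
        vol = make_volume(grid, rng, lesion_mask=m)
        patches = extract_training_patches(vol, mask)
        assert len(patches) == 1
        assert patches[0].n_foreground == 5

    def test_lesion_free_volume_yields_nothing(self, rng):
        grid = VolumeGrid((32, 96, 96), (3, 1, 1))
        mask = LesionMask(grid, np.zeros(grid.shape, dtype=np.uint8))
        vol = make_volume(grid, rng)
        assert extract_training_patches(vol, mask) == []

    def test_matches_brute_force_scan(self, rng):
        grid = VolumeGrid((64, 96, 96), (3, 1, 1))
        m = np.zeros(grid.shape, dtype=np.uint8)
        m[5:8, 10:13, 10:13] = 1     # lesion in first z-cell
        m[40:43, 50:53, 60:63] = 1   # lesion in second z-cell
        mask = LesionMask(grid, m)
        vol = make_volume(grid, rng, lesion_mask=m)
        plan = plan_patches(grid, (32, 96, 96), 0.2)
        patches = extract_training_patches(vol, mask, plan)
        kept = {p.origin for p in patches}
        expected = set()
        for (z, y, x) in plan.origins:
            if m[z:z + 32, y:y + 96, x:x + 96].any():
                expected.add((z, y, x))
        assert kept == expected
        assert len(kept) >= 2

    def test_channel_order_preserved(self, rng):
        grid = VolumeGrid((32, 96, 96), (3, 1, 1))
        m = np.zeros(grid.shape, dtype=np.uint8)
        m[16, 48, 48] = 1
        channels = {"T1p": np.full(grid.shape, 1.0),
                    "T2w": np.full(grid.shape, 2.0),
                    "FLAIR": np.full(grid.shape, 3.0)}
        vol = MultimodalVolume(grid, channels)
        patch = extract_training_patches(vol, LesionMask(grid, m))[0]
        assert patch.data[0].mean() == pytest.approx(1.0)
        assert patch.data[1].mean() == pytest.approx(2.0)
        assert patch.data[2].mean() == pytest.approx(3.0)


class TestAugment:
    def _patch(self, rng, shape=(8, 24, 24)):
        label = np.zeros(shape, dtype=np.uint8)
        label[2:5, 8:14, 8:14] = 1
        data = rng.standard_normal((3,) + shape).astype(np.float32)
        return Patch(data, (0, 0, 0), label)

    def test_probability_zero_is_identity(self, rng):
        p = self._patch(rng)
        out = augment(p, 0, AugmentParams(probability=0.0))
        np.testing.assert_array_equal(out.data, p.data)
        np.testing.assert_array_equal(out.label, p.label)

    def test_label_stays_binary(self, rng):
        p = self._patch(rng)
        params = AugmentParams(probability=1.0)
        out = augment(p, 3, params)
        assert set(np.unique(out.label)) <= {0, 1}

    def test_fair_coin_rate(self, rng):
        p = self._patch(rng)
        params = AugmentParams(probability=0.5)
        n_changed = 0
        stream = np.random.default_rng(99)
        for _ in range(1000):
            out = augment(p, stream, params)
            if not np.array_equal(out.data, p.data):
                n_changed += 1
        # binomial 3 sigma around 500
        assert abs(n_changed - 500) < 50

    def test_foreground_survives_for_27_voxel_blob(self, rng):
        params = AugmentParams(probability=1.0)
        for seed in range(50):
            p = self._patch(rng)
            out = augment(p, seed, params)
            assert out.label.sum() > 0
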