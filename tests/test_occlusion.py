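"""Mask algebra and occluded-tensor construction."""

import numpy as np
import pytest

from tsocclude import (
    DATASET_MEAN,
    FULL,
    OcclusionSpec,
    apply_occlusion,
    build_masks,
    occlude_dataset,
    resolve_occlusion_values,
)
from tsocclude.occlusion import InvalidOffsetError, InvalidWindowError
from .conftest import random_tensor


class TestBuildMasks:
    def test_interior_window(self):
        m = build_masks(h=6, p=2, d=2)
        assert m.keep_mask.tolist() == [1, 1, 0, 0, 1, 1]
        assert m.occlude_mask.tolist() == [0, 0, 1, 1, 0, 0]

    def test_full_occlusion(self):
        m = build_masks(h=4, p=0, d=4)
        assert m.keep_mask.tolist() == [0, 0, 0, 0]

    def test_window_clipped_at_series_end(self):
        m = build_masks(h=5, p=3, d=10)
        assert m.keep_mask.tolist() == [1, 1, 1, 0, 0]

    def test_offset_out_of_range(self):
        with pytest.raises(InvalidOffsetError):
            build_masks(h=5, p=5, d=1)

    def test_complementarity_random(self, rng):
        for _ in range(200):
            h = int(rng.integers(1, 100))
            p = int(rng.integers(0, h))
            d = int(rng.integers(1, h + 10))
            m = build_masks(h, p, d)
            assert np.array_equal(m.keep_mask + m.occlude_mask, np.ones(h))
            assert m.occlude_mask.sum() == min(d, h - p)


class TestApplyOcclusion:
    def test_elementwise_definition(self):
        out = apply_occlusion([1, 2, 3, 4, 5, 6], build_masks(6, 2, 2), ov=0.0)
        assert out.tolist() == [1, 2, 0, 0, 5, 6]

    def test_full_window_gives_constant(self, rng):
        x = rng.normal(size=7)
        out = apply_occlusion(x, build_masks(7, 0, 7), ov=0.0)
        assert np.array_equal(out, np.zeros(7))

    def test_nonzero_ov_substituted(self):
        out = apply_occlusion([1.0, 1.0, 1.0], build_masks(3, 1, 1), ov=9.5)
        assert out.tolist() == [1.0, 9.5, 1.0]


class TestOccludeDataset:
    def test_full_occlusion_zeroes_only_subset(self, small_tensor):
        spec = OcclusionSpec(occlusion_value=0.0, duration=FULL, signal_subset=(1,))
        occ = occlude_dataset(small_tensor, spec)
        assert np.all(occ.values[:, :, 1] == 0)
        others = [0, 2]
        assert np.array_equal(occ.values[:, :, others], small_tensor.values[:, :, others])

    def test_windowed_occlusion_localized(self, small_tensor):
        spec = OcclusionSpec(occlusion_value=0.0, duration=20, window_index=1,
                             signal_subset=(0,))
        occ = occlude_dataset(small_tensor, spec)
        assert np.all(occ.values[:, 20:40, 0] == 0)
        assert np.array_equal(occ.values[:, :20, 0], small_tensor.values[:, :20, 0])
        assert np.array_equal(occ.values[:, 40:, 0], small_tensor.values[:, 40:, 0])
        assert np.array_equal(occ.values[:, :, 1:], small_tensor.values[:, :, 1:])

    def test_input_not_mutated(self, small_tensor):
        before = small_tensor.values.copy()
        occlude_dataset(small_tensor, OcclusionSpec(duration=10, window_index=2))
        assert np.array_equal(small_tensor.values, before)

    def test_idempotence(self, small_tensor):
        spec = OcclusionSpec(occlusion_value=3.3, duration=15, window_index=3,
                             signal_subset=(0, 2))
        once = occlude_dataset(small_tensor, spec)
        twice = occlude_dataset(once, spec)
        assert np.array_equal(once.values, twice.values)

    def test_full_equals_windowed_with_d_h(self, rng):
        for _ in range(25):
            X = random_tensor(rng)
            subset = (int(rng.integers(0, X.n_signals)),)
            full = occlude_dataset(X, OcclusionSpec(duration=FULL, signal_subset=subset))
            windowed = occlude_dataset(
                X, OcclusionSpec(duration=X.n_timesteps, window_index=0,
                                 signal_subset=subset)
            )
            assert np.array_equal(full.values, windowed.values)

    def test_multi_signal_subset(self, small_tensor):
        spec = OcclusionSpec(duration=20, window_index=0, signal_subset=(0, 1))
        occ = occlude_dataset(small_tensor, spec)
        assert np.all(occ.values[:, :20, [0, 1]] == 0)
        assert np.array_equal(occ.values[:, :, 2], small_tensor.values[:, :, 2])

    def test_dataset_mean_is_per_signal(self, small_tensor):
        ov = resolve_occlusion_values(small_tensor, DATASET_MEAN)
        expected = small_tensor.values.mean(axis=(0, 1))
        assert np.allclose(ov, expected)
        occ = occlude_dataset(
            small_tensor, OcclusionSpec(occlusion_value=DATASET_MEAN, duration=FULL,
                                        signal_subset=(0, 1, 2))
        )
        for j in range(3):
            assert np.allclose(occ.values[:, :, j], expected[j])

    def test_window_index_out_of_range(self, small_tensor):
        spec = OcclusionSpec(duration=20, window_index=3)
        with pytest.raises(InvalidWindowError):
            occlude_dataset(small_tensor, spec)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            OcclusionSpec(signal_subset=())
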