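import numpy as np
import pytest
from hypothesis import given, strategies as st

from imlseg import (
    ImageGeometry,
    PreprocessConfig,
    needs_resampling,
    resample_channel,
    resample_labels,
    restore_to_original,
    standardize,
    target_isotropic_spacing,
)
from imlseg.imageio import LabelDrawing
from imlseg.metrics import dice
from imlseg.preprocess import resampled_size


def _geom(size, spacing):
    return ImageGeometry(size=size, spacing=spacing,
                         origin=(0.0,) * len(size))


def _oracle_spacing(geometry, cap, step=0.001):
    """Fine-grid scan from min spacing upward: first spacing under the cap."""
    s = min(geometry.spacing)
    while int(np.prod(resampled_size(geometry, s))) >= cap:
        s += step
    return s


class TestResamplingTrigger:
    @pytest.mark.parametrize("spacing,expected", [
        ((1.0, 1.0, 1.0), False),
        ((0.5, 0.5, 3.0), True),   # 2.5 mm anisotropy > 0.1 margin
        ((1.0, 1.0, 1.05), False),  # 0.05 <= 0.1 margin
        ((1.0, 1.0, 1.1), False),   # exactly at the margin: strict >
        ((1.0, 1.0, 1.11), True),
    ])
    def test_anisotropy_margin(self, spacing, expected):
        geom = _geom((40, 40, 40), spacing)
        assert needs_resampling(geom, PreprocessConfig()) is expected

    def test_large_isotropic_image_triggers(self):
        geom = _geom((220, 220, 220), (1.0, 1.0, 1.0))  # 10.6M voxels
        assert needs_resampling(geom, PreprocessConfig())

    def test_cap_is_strict(self):
        geom = _geom((1000, 100, 100), (1.0, 1.0, 1.0))  # exactly 10M
        assert needs_resampling(geom, PreprocessConfig())


class TestTargetSpacing:
    def test_small_image_keeps_min_spacing(self):
        geom = _geom((40, 40, 40), (1.0, 1.0, 1.0))
        assert target_isotropic_spacing(geom, PreprocessConfig()) == 1.0

    @pytest.mark.parametrize("size,spacing", [
        ((200, 512, 512), (3.0, 0.5, 0.5)),
        ((4000, 4000), (1.0, 1.0)),
        ((300, 400, 500), (1.0, 0.7, 0.4)),
    ])
    def test_matches_fine_grid_oracle(self, size, spacing):
        geom = _geom(size, spacing)
        cfg = PreprocessConfig()
        s = target_isotropic_spacing(geom, cfg)
        oracle = _oracle_spacing(geom, cfg.voxel_cap)
        assert s >= min(spacing)
        assert int(np.prod(resampled_size(geom, s))) < cfg.voxel_cap
        # agreement within one 0.01 mm search step
        assert abs(s - oracle) <= 0.01 + 1e-9

    @given(cap=st.integers(min_value=10_000, max_value=20_000_000))
    def test_monotone_in_cap(self, cap):
        geom = _geom((200, 512, 512), (3.0, 0.5, 0.5))
        s_small = target_isotropic_spacing(geom, PreprocessConfig(voxel_cap=cap))
        s_large = target_isotropic_spacing(
            geom, PreprocessConfig(voxel_cap=cap * 2))
        assert s_large <= s_small + 1e-12


class TestResample:
    def test_constant_image_stays_constant(self):
        geom = _geom((16, 16), (1.0, 2.0))
        arr = np.full((16, 16), 3.5)
        out, new_geom = resample_channel(arr, geom, 1.0)
        np.testing.assert_allclose(out, 3.5, atol=1e-6)
        assert new_geom.spacing == (1.0, 1.0)

    def test_identity_resample_preserves_values(self):
        geom = _geom((10, 12), (1.5, 1.5))
        arr = np.random.default_rng(1).normal(size=(10, 12))
        out, new_geom = resample_channel(arr, geom, 1.5)
        assert new_geom.size == geom.size
        np.testing.assert_allclose(out, arr, atol=1e-6)

    def test_linear_ramp_downsampled_matches_analytic(self):
        # I(z, y) = physical y coordinate; linear interpolation is exact
        geom = _geom((8, 64), (1.0, 1.0))
        y_mm = np.arange(64) * 1.0
        arr = np.tile(y_mm, (8, 1))
        out, new_geom = resample_channel(arr, geom, 2.0)
        expect = np.tile(np.arange(new_geom.size[1]) * 2.0, (new_geom.size[0], 1))
        interior = out[:, :-1]  # last column may sit outside the source extent
        np.testing.assert_allclose(interior, expect[:, :-1], atol=1e-6)

    def test_labels_keep_value_set(self):
        geom = _geom((20, 20), (1.0, 1.0))
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        drawing = LabelDrawing(labels=labels, geometry=geom)
        out = resample_labels(drawing, 3.0)
        assert set(np.unique(out.labels)) <= {0, 1, 2}
        assert out.labels.dtype == np.int32

    def test_single_voxel_label_may_vanish(self):
        geom = _geom((16, 16), (1.0, 1.0))
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[5, 5] = 1
        out = resample_labels(LabelDrawing(labels=labels, geometry=geom), 4.0)
        assert set(np.unique(out.labels)) <= {0, 1}


class TestStandardize:
    def test_three_point_example(self):
        out = standardize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487],
                                   atol=1e-8)

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(standardize(np.full((4, 4), 9.0)),
                                      np.zeros((4, 4)))

    @given(st.integers(min_value=0, max_value=1000))
    def test_zero_mean_unit_sd(self, seed):
        arr = np.random.default_rng(seed).normal(2.0, 5.0, size=200)
        out = standardize(arr)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_idempotent(self, rng):
        arr = rng.normal(size=(8, 8))
        once = standardize(arr)
        np.testing.assert_allclose(standardize(once), once, atol=1e-6)


class TestRestore:
    def test_identity_when_grids_match(self):
        geom = _geom((8, 8), (1.0, 1.0))
        pred = np.arange(64, dtype=np.int32).reshape(8, 8) % 3
        np.testing.assert_array_equal(
            restore_to_original(pred, geom, geom), pred)

    def test_sphere_roundtrip_dice(self):
        # downsample a 40-voxel-radius sphere x2 and restore: Dice >= 0.95
        geom = _geom((96, 96, 96), (1.0, 1.0, 1.0))
        z, y, x = np.ogrid[:96, :96, :96]
        blob = (((z - 48) ** 2 + (y - 48) ** 2 + (x - 48) ** 2)
                <= 40 ** 2).astype(np.int32)
        down = resample_labels(LabelDrawing(labels=blob, geometry=geom), 2.0)
        restored = restore_to_original(down.labels, down.geometry, geom)
        assert dice(restored, blob, 1) >= 0.95

    def test_restored_labels_subset_of_working(self):
        geom = _geom((12, 12), (1.0, 1.0))
        work = _geom((6, 6), (2.0, 2.0))
        pred = np.random.default_rng(3).integers(0, 3, size=(6, 6)).astype(np.int32)
        restored = restore_to_original(pred, work, geom)
        assert set(np.unique(restored)) <= set(np.unique(pred))
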