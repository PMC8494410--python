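import numpy as np
import pytest

from imlseg import (
    AGDParams,
    EmptySeedsError,
    ImageGeometry,
    MissingClassError,
    agd_map,
    all_agd_maps,
    normalize01,
)
from imlseg.agd import dijkstra_reference
from imlseg.imageio import LabelDrawing, MultiChannelImage

CONVERGED = AGDParams(intensity_weight=1.0, max_passes=64)


def _geom(size, spacing=None):
    spacing = spacing or (1.0,) * len(size)
    return ImageGeometry(size=size, spacing=spacing, origin=(0.0,) * len(size))


def test_row_image_matches_hand_computed_path_costs():
    # steps cost 1 mm + |dI|: 0 -> 1 -> 3 -> 4 along the row
    geom = _geom((1, 4))
    intensity = np.array([[0.0, 0.0, 1.0, 1.0]])
    seeds = np.zeros((1, 4), dtype=bool)
    seeds[0, 0] = True
    out = agd_map(intensity, geom, seeds, CONVERGED)
    np.testing.assert_allclose(out, [[0.0, 1.0, 3.0, 4.0]], atol=1e-12)


def test_constant_image_reduces_to_spatial_geodesic():
    geom = _geom((9, 9), spacing=(2.0, 1.0))
    channel = np.zeros((9, 9))
    seeds = np.zeros((9, 9), dtype=bool)
    seeds[4, 4] = True
    out = agd_map(channel, geom, seeds, CONVERGED)
    ref = dijkstra_reference(channel, geom, seeds,
                             AGDParams(intensity_weight=0.0))
    np.testing.assert_allclose(out, ref, atol=1e-9)
    # corner: 4 diagonal steps of sqrt(2^2 + 1^2)
    assert out[0, 0] == pytest.approx(4 * np.sqrt(5.0))


def test_all_seeded_gives_zero_map():
    geom = _geom((5, 5))
    out = agd_map(np.random.default_rng(0).normal(size=(5, 5)), geom,
                  np.ones((5, 5), dtype=bool), CONVERGED)
    np.testing.assert_array_equal(out, np.zeros((5, 5)))


def test_empty_seeds_rejected():
    geom = _geom((4, 4))
    with pytest.raises(EmptySeedsError):
        agd_map(np.zeros((4, 4)), geom, np.zeros((4, 4), dtype=bool))


@pytest.mark.parametrize("shape", [(16, 16), (8, 8, 8)])
def test_sweep_equals_dijkstra_on_random_fields(shape, rng):
    geom = _geom(shape)
    for _ in range(10):
        channel = rng.normal(size=shape)
        seeds = np.zeros(shape, dtype=bool)
        seeds[tuple(rng.integers(0, shape[0], size=len(shape)))] = True
        sweep = agd_map(channel, geom, seeds, CONVERGED)
        exact = dijkstra_reference(channel, geom, seeds, CONVERGED)
        np.testing.assert_allclose(sweep, exact, atol=1e-9)


def test_triangle_bound_after_convergence(rng):
    geom = _geom((12, 12))
    channel = rng.normal(size=(12, 12))
    seeds = np.zeros((12, 12), dtype=bool)
    seeds[3, 7] = True
    d = agd_map(channel, geom, seeds, CONVERGED)
    lam = CONVERGED.intensity_weight
    for dz in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dz == 0 and dx == 0:
                continue
            step = np.hypot(dz, dx)
            a = d[max(0, dz):12 + min(0, dz) or None,
                  max(0, dx):12 + min(0, dx) or None]
            b = d[max(0, -dz):12 + min(0, -dz) or None,
                  max(0, -dx):12 + min(0, -dx) or None]
            ia = channel[max(0, dz):12 + min(0, dz) or None,
                         max(0, dx):12 + min(0, dx) or None]
            ib = channel[max(0, -dz):12 + min(0, -dz) or None,
                         max(0, -dx):12 + min(0, -dx) or None]
            assert np.all(a <= b + step + lam * np.abs(ia - ib) + 1e-9)


def test_raising_intensity_weight_never_decreases_distances(rng):
    geom = _geom((10, 10))
    channel = rng.normal(size=(10, 10))
    seeds = np.zeros((10, 10), dtype=bool)
    seeds[0, 0] = True
    lo = agd_map(channel, geom, seeds, AGDParams(1.0, 64))
    hi = agd_map(channel, geom, seeds, AGDParams(2.0, 64))
    assert np.all(hi >= lo - 1e-12)


def test_adding_seeds_never_increases_values(rng):
    geom = _geom((10, 10))
    channel = rng.normal(size=(10, 10))
    seeds = np.zeros((10, 10), dtype=bool)
    seeds[2, 2] = True
    base = agd_map(channel, geom, seeds, CONVERGED)
    seeds[7, 7] = True
    more = agd_map(channel, geom, seeds, CONVERGED)
    assert np.all(more <= base + 1e-12)


class TestNormalize:
    def test_affine_example(self):
        np.testing.assert_allclose(
            normalize01(np.array([0.0, 1.0, 3.0, 4.0])),
            [0.0, 0.25, 0.75, 1.0])

    def test_constant_map_to_zeros(self):
        np.testing.assert_array_equal(normalize01(np.zeros(5)), np.zeros(5))

    def test_range_is_unit(self, rng):
        out = normalize01(rng.normal(size=(6, 6)))
        assert out.min() == 0.0
        assert out.max() == 1.0


class TestStack:
    def _image_and_drawing(self, rng):
        geom = _geom((10, 10))
        channels = tuple(rng.normal(size=(10, 10)) for _ in range(2))
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[1, 1] = 1
        labels[5, 5] = 2
        labels[8, 8] = 3
        return (MultiChannelImage(channels=channels, geometry=geom),
                LabelDrawing(labels=labels, geometry=geom))

    def test_one_map_per_channel_label_pair(self, rng):
        image, drawing = self._image_and_drawing(rng)
        stack = all_agd_maps(image, drawing)
        assert stack.maps.shape[:2] == (2, 3)
        assert stack.label_ids == (1, 2, 3)
        assert stack.maps.min() >= 0.0 and stack.maps.max() <= 1.0
        # maps vanish at their own seeds
        for li, lab in enumerate(stack.label_ids):
            seed_mask = drawing.labels == lab
            for ci in range(2):
                assert np.all(stack.maps[ci, li][seed_mask] == 0.0)

    def test_channel_permutation_permutes_maps(self, rng):
        image, drawing = self._image_and_drawing(rng)
        stack = all_agd_maps(image, drawing)
        flipped = MultiChannelImage(channels=image.channels[::-1],
                                    geometry=image.geometry)
        stack_flipped = all_agd_maps(flipped, drawing)
        np.testing.assert_array_equal(stack.maps[0], stack_flipped.maps[1])
        np.testing.assert_array_equal(stack.maps[1], stack_flipped.maps[0])

    def test_missing_class_is_reported_by_id(self, rng):
        geom = _geom((6, 6))
        image = MultiChannelImage(
            channels=(rng.normal(size=(6, 6)),), geometry=geom)
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[0, 0] = 1
        drawing = LabelDrawing(labels=labels, geometry=geom)
        with pytest.raises(MissingClassError):
            all_agd_maps(image, drawing)
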