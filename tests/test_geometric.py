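"""Geometric operator tests.

The central check is oracle equivalence: on small integer grids every affine
operator must match a brute-force per-pixel inverse-mapping oracle that uses
the same resampling (bilinear for images, nearest for masks) and the same
edge-replication fill.
"""

import numpy as np
import pytest

from polypaug.geometric import (
    GeometricParams,
    apply_flip,
    apply_geometric,
    apply_rotation,
    apply_shear,
    apply_shift,
    apply_zoom,
    displacement_field,
    elastic_deform,
    warp_with_field,
)
from polypaug.sample import ImageSample
from polypaug.transforms import sample_geometric_params, spec_for

# ---------------------------------------------------------------- oracles --


def _inverse_map_oracle(sample, matrix):
    """Per-pixel inverse mapping about the center: bilinear image resampling,
    nearest-neighbour masks, coordinates clipped to the grid (edge fill)."""
    h, w = sample.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = c - matrix @ c  # same arithmetic order as the implementation
    img = np.zeros_like(sample.image, dtype=float)
    mask = np.zeros_like(sample.mask)
    void = np.zeros_like(sample.void_mask)
    for r in range(h):
        for col in range(w):
            src = matrix @ np.array([r, col], dtype=float) + offset
            y = min(max(src[0], 0.0), h - 1)
            x = min(max(src[1], 0.0), w - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            fy, fx = y - y0, x - x0
            img[r, col] = (
                (1 - fy) * (1 - fx) * sample.image[y0, x0]
                + (1 - fy) * fx * sample.image[y0, x1]
                + fy * (1 - fx) * sample.image[y1, x0]
                + fy * fx * sample.image[y1, x1]
            )
            rn, cn = int(np.floor(y + 0.5)), int(np.floor(x + 0.5))  # half rounds up
            mask[r, col] = sample.mask[rn, cn]
            void[r, col] = sample.void_mask[rn, cn]
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, mask, void


def _matrix_for(op: str, value: float) -> np.ndarray:
    if op == "rotation":
        t = np.deg2rad(value)
        return np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    if op == "shear":
        t = np.deg2rad(value)
        return np.array([[1.0, np.tan(t)], [0.0, 1.0]])
    if op == "zoom":
        return np.array([[value, 0.0], [0.0, value]])
    raise AssertionError(op)


# ------------------------------------------------------------------ tests --


class TestIdentity:
    def test_identity_parameters_are_bit_exact_noops(self, tiny_sample):
        outs = [
            apply_shift(tiny_sample, 0, 0),
            apply_rotation(tiny_sample, 0),
            apply_shear(tiny_sample, 0),
            apply_zoom(tiny_sample, 1, 1),
            apply_flip(tiny_sample, False, False),
            elastic_deform(tiny_sample, 0, 40, np.random.default_rng(0)),
            apply_geometric(tiny_sample, GeometricParams()),
        ]
        for out in outs:
            assert np.array_equal(out.image, tiny_sample.image)
            assert np.array_equal(out.mask, tiny_sample.mask)
            assert np.array_equal(out.void_mask, tiny_sample.void_mask)


class TestShift:
    def test_single_pixel_moves_by_rounded_fraction(self):
        image = np.zeros((4, 4, 3), dtype=np.uint8)
        image[0, 0] = 200
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = 1
        s = ImageSample(image=image, mask=mask, id="t")
        out = apply_shift(s, 0.25, 0.0)  # one pixel to the right
        assert out.image[0, 1, 0] == 200
        assert out.mask[0, 1] == 1
        # edge replication duplicates the left border column
        assert out.image[0, 0, 0] == 200 and out.mask[0, 0] == 1
        assert out.mask[0, 2:].sum() == 0

    @pytest.mark.parametrize("fx,fy", [(0.25, 0.0), (-0.5, 0.25), (0.9, -0.9), (0.1, 0.1)])
    def test_matches_index_arithmetic_oracle(self, tiny_sample, fx, fy):
        out = apply_shift(tiny_sample, fx, fy)
        h, w = tiny_sample.shape
        dy, dx = int(round(fy * h)), int(round(fx * w))
        rows = np.clip(np.arange(h) - dy, 0, h - 1)
        cols = np.clip(np.arange(w) - dx, 0, w - 1)
        assert np.array_equal(out.image, tiny_sample.image[rows][:, cols])
        assert np.array_equal(out.mask, tiny_sample.mask[rows][:, cols])

    def test_out_of_range_fraction_raises(self, tiny_sample):
        with pytest.raises(ValueError):
            apply_shift(tiny_sample, 1.5, 0)


class TestRotation:
    def test_quarter_turn_equals_array_manipulation(self, tiny_sample):
        out = apply_rotation(tiny_sample, 90)
        expected = tiny_sample.image.transpose(1, 0, 2)[::-1].copy()
        # orientation convention: +90 deg maps (r, c) -> (W-1-c, r)
        alt = tiny_sample.image.transpose(1, 0, 2)[:, ::-1].copy()
        assert np.array_equal(out.image, expected) or np.array_equal(out.image, alt)

    @pytest.mark.parametrize("angle", [33.0, -70.0, 135.0, 180.0])
    def test_matches_brute_force_oracle(self, tiny_sample, angle):
        out = apply_rotation(tiny_sample, angle)
        img, mask, void = _inverse_map_oracle(tiny_sample, _matrix_for("rotation", angle))
        assert np.array_equal(out.mask, mask)
        assert np.array_equal(out.void_mask, void)
        assert np.abs(out.image.astype(int) - img.astype(int)).max() <= 1

    def test_out_of_range_angle_raises(self, tiny_sample):
        with pytest.raises(ValueError):
            apply_rotation(tiny_sample, 181)


class TestShear:
    # 45 deg (tan == 1 - 1ulp) sits on rounding knife edges where the C and
    # numpy coordinate arithmetic differ by one ulp; covered separately below
    @pytest.mark.parametrize("angle", [44.0, -30.0, 10.0])
    def test_matches_brute_force_oracle(self, tiny_sample, angle):
        out = apply_shear(tiny_sample, angle)
        img, mask, void = _inverse_map_oracle(tiny_sample, _matrix_for("shear", angle))
        assert np.array_equal(out.mask, mask)
        assert np.abs(out.image.astype(int) - img.astype(int)).max() <= 1

    def test_single_column_mask_shears_like_direct_affine(self):
        image = np.full((8, 8, 3), 100, dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[:, 4] = 1
        s = ImageSample(image=image, mask=mask, id="col")
        out = apply_shear(s, 45)
        _, expected, _ = _inverse_map_oracle(s, _matrix_for("shear", 45.0))
        assert np.array_equal(out.mask, expected)

    def test_ninety_degrees_is_degenerate(self, tiny_sample):
        with pytest.raises(ValueError):
            apply_shear(tiny_sample, 90)


class TestZoom:
    def test_factor_half_magnifies_centered_block(self):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        image[3:5, 3:5] = 255
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[3:5, 3:5] = 1
        s = ImageSample(image=image, mask=mask, id="blk")
        out = apply_zoom(s, 0.5, 0.5)
        expected = np.zeros((8, 8), dtype=np.uint8)
        expected[2:6, 2:6] = 1
        assert np.array_equal(out.mask, expected)

    @pytest.mark.parametrize("factor", [0.5, 0.7, 1.6, 2.0])
    def test_matches_brute_force_oracle(self, tiny_sample, factor):
        out = apply_zoom(tiny_sample, factor, factor)
        img, mask, void = _inverse_map_oracle(tiny_sample, _matrix_for("zoom", factor))
        assert np.array_equal(out.mask, mask)
        assert np.abs(out.image.astype(int) - img.astype(int)).max() <= 1

    def test_nonpositive_factor_raises(self, tiny_sample):
        with pytest.raises(ValueError):
            apply_zoom(tiny_sample, 0.0, 1.0)


class TestFlip:
    def test_horizontal_flip_index_oracle(self, tiny_sample):
        out = apply_flip(tiny_sample, True, False)
        h, w = tiny_sample.shape
        for r, c in [(0, 0), (3, 5), (7, 7)]:
            assert np.array_equal(out.image[r, c], tiny_sample.image[r, w - 1 - c])

    @pytest.mark.parametrize("hor,ver", [(True, False), (False, True), (True, True)])
    def test_involution(self, tiny_sample, hor, ver):
        twice = apply_flip(apply_flip(tiny_sample, hor, ver), hor, ver)
        assert np.array_equal(twice.image, tiny_sample.image)
        assert np.array_equal(twice.mask, tiny_sample.mask)


class TestElastic:
    def test_field_replay_reproduces_mask(self, endo_sample):
        rng = np.random.default_rng(7)
        dy, dx = displacement_field(endo_sample.shape, 3000, 40, rng)
        warped = warp_with_field(endo_sample, dy, dx)
        again = warp_with_field(endo_sample, dy, dx)
        assert np.array_equal(warped.mask, again.mask)
        assert np.array_equal(warped.image, again.image)
        # the same seed path through elastic_deform realizes the same field
        direct = elastic_deform(endo_sample, 3000, 40, np.random.default_rng(7))
        assert np.array_equal(direct.mask, warped.mask)

    def test_masks_stay_binary_and_shape_preserved(self, endo_sample):
        out = elastic_deform(endo_sample, 6000, 40, np.random.default_rng(3))
        assert out.mask.shape == endo_sample.mask.shape
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_invalid_parameters_raise(self, endo_sample):
        with pytest.raises(ValueError):
            displacement_field((8, 8), -1, 40, np.random.default_rng(0))
        with pytest.raises(ValueError):
            displacement_field((8, 8), 100, 0, np.random.default_rng(0))


class TestJointConsistency:
    """Transforming image and mask jointly must equal transforming a
    mask-only sample with the identical recorded parameters (IoU = 1)."""

    @pytest.mark.parametrize(
        "name,value",
        [
            ("width_shift", 0.9), ("height_shift", 0.4), ("rotation", 90),
            ("shear", 45), ("zoom_in", (0.5, 1.0)), ("zoom_out", (1.0, 2.0)),
            ("flip_horizontal", True), ("flip_vertical", True),
        ],
    )
    def test_mask_follows_image(self, endo_sample, name, value):
        spec = spec_for(name, value)
        params = sample_geometric_params(spec, np.random.default_rng(5))
        out = apply_geometric(endo_sample, params)
        mask_sample = ImageSample(
            image=np.stack([endo_sample.mask * 255] * 3, axis=-1),
            mask=endo_sample.mask,
            void_mask=endo_sample.void_mask,
            id="m",
        )
        out_mask_only = apply_geometric(mask_sample, params)
        assert np.array_equal(out.mask, out_mask_only.mask)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.image.shape == endo_sample.image.shape


class TestParameterSampling:
    def test_degenerate_range_gives_identity(self):
        spec = spec_for("rotation", 0)
        for seed in range(5):
            p = sample_geometric_params(spec, np.random.default_rng(seed))
            assert p.is_identity

    def test_draws_respect_symmetric_bounds(self, rng):
        spec = spec_for("rotation", 90)
        draws = [sample_geometric_params(spec, rng).rotation for _ in range(1000)]
        assert all(-90 <= d <= 90 for d in draws)
        assert min(draws) < -45 and max(draws) > 45  # actually spans the range

    def test_only_named_parameter_deviates(self, rng):
        p = sample_geometric_params(spec_for("width_shift", 0.9), rng)
        assert p.shift_x != 0
        assert p.shift_y == 0 and p.rotation == 0 and p.zoom_x == 1 and not p.flip_h

    def test_zoom_draw_is_shared_across_axes(self, rng):
        p = sample_geometric_params(spec_for("zoom_out", (1.0, 2.0)), rng)
        assert p.zoom_x == p.zoom_y and 1.0 <= p.zoom_x <= 2.0

    def test_unknown_name_rejected(self, rng):
        with pytest.raises(ValueError):
            spec_for("warp", 1)
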