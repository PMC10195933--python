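"""Preprocessing chain: orientation, padding, windowing, resizing, and
exact coordinate bookkeeping."""

import json

import numpy as np
import pytest

from mammoqa import preprocess as pp
from mammoqa.records import ImageRecord


def make_record(rows=60, cols=40, breast_side="left", laterality="R",
                spacing=(0.5, 0.5), seed=0):
    """Synthetic record with tissue concentrated on one side."""
    rng = np.random.default_rng(seed)
    img = rng.uniform(0.0, 0.05, (rows, cols))
    cols_half = cols // 2
    if breast_side == "left":
        img[:, :cols_half] += 0.5
    else:
        img[:, cols_half:] += 0.5
    return ImageRecord(np.clip(img, 0, 1), spacing, "CC", laterality, "t")


class TestOrientation:
    def test_right_facing_breast_is_flipped(self):
        rec = make_record(breast_side="right", laterality="L")
        out, log = pp.standardize_orientation(rec)
        assert log.steps and log.steps[0]["op"] == "hflip"
        np.testing.assert_array_equal(out.pixels, rec.pixels[:, ::-1])

    def test_canonical_image_unchanged_and_idempotent(self):
        rec = make_record(breast_side="left")
        out, log = pp.standardize_orientation(rec)
        assert log.steps == []
        np.testing.assert_array_equal(out.pixels, rec.pixels)
        out2, log2 = pp.standardize_orientation(out)
        assert log2.steps == []

    def test_flip_twice_restores(self):
        rec = make_record(breast_side="right")
        out, _ = pp.standardize_orientation(rec)
        # the flipped image now faces left; mirroring manually restores
        np.testing.assert_array_equal(out.pixels[:, ::-1], rec.pixels)

    def test_unknown_laterality_rejected(self):
        rec = make_record()
        rec.laterality = "?"
        with pytest.raises(pp.MetadataError):
            pp.standardize_orientation(rec)


class TestPadToSquare:
    def test_portrait_gains_right_stripe(self):
        rec = make_record(rows=50, cols=30)
        out, log = pp.pad_to_square(rec)
        assert out.pixels.shape == (50, 50)
        assert log.steps[-1] == {"op": "pad", "right_px": 20, "bottom_px": 0}
        np.testing.assert_array_equal(out.pixels[:, :30], rec.pixels)
        assert np.all(out.pixels[:, 30:] == 0.0)

    def test_square_unchanged(self):
        rec = make_record(rows=40, cols=40)
        out, log = pp.pad_to_square(rec)
        assert log.steps == []
        np.testing.assert_array_equal(out.pixels, rec.pixels)

    def test_landscape_padded_at_bottom(self):
        rec = make_record(rows=30, cols=50)
        out, _ = pp.pad_to_square(rec)
        assert out.pixels.shape == (50, 50)
        np.testing.assert_array_equal(out.pixels[:30], rec.pixels)
        assert np.all(out.pixels[30:] == 0.0)

    def test_padding_does_not_move_content_coordinates(self):
        rec = make_record(rows=50, cols=30)
        _, log = pp.pad_to_square(rec)
        pt = log.forward_px((29.0, 10.0))
        np.testing.assert_allclose(pt, (29.0, 10.0))


class TestWindow:
    def test_identity_window(self):
        rec = make_record()
        out = pp.apply_window(rec, 0.0, 1.0)
        np.testing.assert_allclose(out.pixels, rec.pixels)

    def test_linear_map(self):
        rec = make_record()
        rec.pixels[0, 0] = 0.5
        out = pp.apply_window(rec, 0.25, 0.75)
        assert out.pixels[0, 0] == pytest.approx(0.5)

    def test_clipping(self):
        rec = make_record()
        rec.pixels[0, 0] = 0.1
        rec.pixels[0, 1] = 0.9
        out = pp.apply_window(rec, 0.25, 0.75)
        assert out.pixels[0, 0] == 0.0
        assert out.pixels[0, 1] == 1.0

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, 256)
        rec = ImageRecord(vals.reshape(16, 16), (1, 1), "CC", "R", "t")
        out = pp.apply_window(rec, 0.2, 0.8)
        order = np.argsort(vals)
        mapped = out.pixels.ravel()[order]
        assert np.all(np.diff(mapped) >= -1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            pp.apply_window(make_record(), 0.7, 0.7)


class TestResize:
    def test_downscale_records_scale(self):
        rec = make_record(rows=448, cols=448)
        out, log = pp.resize_to_model(rec, 224)
        assert out.pixels.shape == (224, 224)
        assert log.steps[-1] == {"op": "resize", "sy": 0.5, "sx": 0.5}

    def test_identity_side(self):
        rec = make_record(rows=64, cols=64)
        out, log = pp.resize_to_model(rec, 64)
        assert log.steps == []
        np.testing.assert_array_equal(out.pixels, rec.pixels)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            pp.resize_to_model(make_record(rows=50, cols=30), 32)


class TestCrop:
    def test_crop_size_is_fraction_of_dims(self):
        rec = make_record(rows=100, cols=200, spacing=(1, 1))
        out = pp.crop_nipple_region(rec, (100.0, 50.0), fraction=0.10)
        assert out.pixels.shape == (10, 20)

    def test_corner_nipple_zero_padded(self):
        rec = make_record(rows=100, cols=100, spacing=(1, 1))
        out = pp.crop_nipple_region(rec, (0.0, 0.0), fraction=0.2)
        assert out.pixels.shape == (20, 20)
        assert np.all(out.pixels[:10, :10] == 0.0) or np.all(out.pixels[:9, :9] == 0.0)

    def test_full_fraction_centered_returns_whole_image(self):
        rec = make_record(rows=101, cols=101, spacing=(1, 1))
        out = pp.crop_nipple_region(rec, (50.0, 50.0), fraction=1.0)
        np.testing.assert_array_equal(out.pixels, rec.pixels)

    def test_outside_nipple_rejected(self):
        rec = make_record(rows=50, cols=50, spacing=(1, 1))
        with pytest.raises(pp.CoordinateError):
            pp.crop_nipple_region(rec, (500.0, 10.0))


class TestMapCoords:
    def test_empty_log_identity(self):
        log = pp.TransformLog((1, 1))
        np.testing.assert_allclose(pp.map_coords((3.5, 7.25), log), (3.5, 7.25))

    def test_hflip_pixel_center_convention(self):
        log = pp.TransformLog((1, 1), [{"op": "hflip", "width_px": 100}])
        np.testing.assert_allclose(pp.map_coords((10, 42), log), (89, 42))

    def test_resize_scaling(self):
        log = pp.TransformLog((1, 1), [{"op": "resize", "sy": 0.5, "sx": 0.5}])
        np.testing.assert_allclose(pp.map_coords((10, 20), log), (5, 10))

    def test_forward_inverse_identity(self):
        log = pp.TransformLog((0.2, 0.3), [
            {"op": "hflip", "width_px": 400},
            {"op": "window", "lo": 0.1, "hi": 0.9},
            {"op": "pad", "right_px": 100, "bottom_px": 0},
            {"op": "resize", "sy": 224 / 500, "sx": 224 / 500},
        ])
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 399, (50, 2))
        for p in pts:
            back = log.inverse_px(log.forward_px(p))
            np.testing.assert_allclose(back, p, atol=1e-9)

    def test_json_round_trip(self):
        log = pp.TransformLog((0.2, 0.3), [{"op": "hflip", "width_px": 17}])
        log2 = pp.TransformLog.from_json(log.to_json())
        assert log2.steps == log.steps
        assert log2.source_spacing_mm == (0.2, 0.3)


def test_full_chain_round_trip_many_random_cases():
    """Flip + window + pad + resize: landmark round-trip under 0.5 px."""
    rng = np.random.default_rng(11)
    worst = 0.0
    for _ in range(200):
        rows = int(rng.integers(40, 160))
        cols = int(rng.integers(30, rows + 1))
        rec = make_record(rows=rows, cols=cols,
                          breast_side=rng.choice(["left", "right"]),
                          laterality=rng.choice(["L", "R"]),
                          seed=int(rng.integers(0, 2**31 - 1)))
        out, log = pp.preprocess_for_model(rec, side_px=32)
        pts = np.column_stack([rng.uniform(0, cols - 1, 5),
                               rng.uniform(0, rows - 1, 5)])
        for p in pts:
            err = np.abs(log.inverse_px(log.forward_px(p)) - p).max()
            worst = max(worst, err)
    assert worst < 0.5


def test_preprocess_for_model_output_contract(mlo_phantom):
    rec, _ = mlo_phantom
    out, log = pp.preprocess_for_model(rec, side_px=96)
    assert out.pixels.shape == (96, 96)
    assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
    ops = [s["op"] for s in log.steps]
    assert "window" in ops and "resize" in ops
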