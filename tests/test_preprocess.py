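import numpy as np
import pytest

from snetseg.io_ct import SliceSample
from snetseg.preprocess import (GeometricAugConfig, GeometricTransform,
                                PreprocessConfig, apply_geometric,
                                contrast_filter, flip_point_to_point,
                                geometric_augment, grayscale_float,
                                prepare_network_input, slice_contrast,
                                window_and_normalize)


def test_window_endpoints():
    img = np.array([[-1000.0, -45.0, 30.0, 105.0, 3000.0]])
    out = window_and_normalize(img, (-45.0, 105.0))
    assert out[0, 0] == 0.0 and out[0, 1] == 0.0
    assert out[0, 2] == pytest.approx(0.5)
    assert out[0, 3] == 1.0 and out[0, 4] == 1.0


def test_window_degenerate_raises():
    with pytest.raises(ValueError):
        window_and_normalize(np.zeros((2, 2)), (10.0, 10.0))


def test_flip_endpoints_and_background():
    img = np.array([[0, 255], [100, 42]], dtype=np.uint8)
    fg = np.array([[True, True], [True, False]])
    out = flip_point_to_point(img, fg)
    assert out[0, 0] == 255 and out[0, 1] == 0
    assert out[1, 0] == 155
    assert out[1, 1] == 0  # background forced to black


def test_flip_involution(rng):
    for _ in range(100):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        fg = rng.random((16, 16)) < 0.6
        twice = flip_point_to_point(flip_point_to_point(img, fg), fg)
        assert np.array_equal(twice[fg], img[fg])
        assert (twice[~fg] == 0).all()


def test_flip_range_check():
    with pytest.raises(ValueError):
        flip_point_to_point(np.array([[300.0]]), np.array([[True]]))


def test_grayscale_float_range(rng):
    img = rng.random((8, 8))
    out = grayscale_float(img, rng)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_right_angle_rotation_preserves_counts(rng):
    mask = rng.random((16, 16)) < 0.3
    img = rng.random((16, 16))
    for k in (90.0, 180.0, 270.0):
        t = GeometricTransform(angle_deg=k)
        _, (m,) = apply_geometric(img, [mask], t)
        assert m.sum() == mask.sum()


def test_integer_shift_exact():
    img = np.zeros((8, 8))
    img[2, 2] = 1.0
    t = GeometricTransform(shift=(1.0, 2.0))
    out, _ = apply_geometric(img, [], t)
    assert out[3, 4] == pytest.approx(1.0)


def test_geometric_augment_disabled_is_identity(rng):
    cfg = GeometricAugConfig(rotation_max_deg=0, translation_max_px=0,
                             mirror=False, shear_max=0)
    img = rng.random((8, 8))
    mask = rng.random((8, 8)) < 0.5
    out, (m,) = geometric_augment(img, [mask], rng, cfg)
    assert out is img and m is mask


def _slice(image, liver, tumor, idx=0):
    return SliceSample(image=image, liver_mask=liver, tumor_mask=tumor,
                       case_id="t", slice_index=idx)


def test_slice_contrast_and_filter():
    liver = np.ones((6, 6), bool)
    tumor = np.zeros((6, 6), bool)
    tumor[2:4, 2:4] = True
    img = np.full((6, 6), 60.0)
    img[tumor] = 40.0  # contrast 20
    keep = _slice(img, liver, tumor, 0)
    img_low = np.full((6, 6), 60.0)
    img_low[tumor] = 55.0  # contrast 5
    drop = _slice(img_low, liver, tumor, 1)
    no_tumor = _slice(img, liver, np.zeros((6, 6), bool), 2)

    assert slice_contrast(keep) == pytest.approx(20.0)
    assert slice_contrast(drop) == pytest.approx(5.0)
    assert slice_contrast(no_tumor) == np.inf

    out = contrast_filter([keep, drop, no_tumor], threshold=10.0)
    assert [s.slice_index for s in out] == [0, 2]


def test_contrast_filter_threshold_tie():
    liver = np.ones((4, 4), bool)
    tumor = np.zeros((4, 4), bool)
    tumor[1, 1] = True
    img = np.full((4, 4), 60.0)
    img[tumor] = 50.0  # contrast exactly 10 -> kept (>= threshold)
    s = _slice(img, liver, tumor)
    assert contrast_filter([s], threshold=10.0) == [s]


def test_prepare_network_input_contract():
    cfg = PreprocessConfig()
    img = np.full((8, 8), 60.0)
    liver = np.zeros((8, 8), bool)
    liver[2:6, 2:6] = True
    out = prepare_network_input(img, liver, cfg)
    assert out.shape == img.shape
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert (out[~liver] == 0.0).all()
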