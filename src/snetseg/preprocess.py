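"""Slice preprocessing: HU windowing, point-to-point flip, grayscale
float, geometric augmentation and the low-contrast slice filter.

The deterministic steps (windowing, flip) are applied identically at
train and inference time; grayscale float and the geometric transforms
are train-time augmentations sampled fresh each epoch; the contrast
filter is applied to the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_ct import SliceSample


@dataclass
class GeometricAugConfig:
    # gentle defaults sized for ~64 px training slices; scale up for
    # full-resolution CT
    rotation_max_deg: float = 5.0
    translation_max_px: int = 2
    mirror: bool = True
    shear_max: float = 0.02

    def validate(self):
        if min(self.rotation_max_deg, self.translation_max_px, self.shear_max) < 0:
            raise ValueError("augmentation maxima must be >= 0")


@dataclass
class PreprocessConfig:
    """Window, flip and augmentation settings for one experiment."""

    # soft-tissue window (width 150, level 30): the standard liver window
    hu_window: tuple[float, float] = (-45.0, 105.0)
    flip_enabled: bool = True
    gray_float_enabled: bool = True
    geometric_aug: GeometricAugConfig = field(default_factory=GeometricAugConfig)
    contrast_filter_threshold: float = 10.0
    seed: int = 0

    def validate(self):
        lo, hi = self.hu_window
        if lo >= hi:
            raise ValueError(f"degenerate HU window ({lo}, {hi})")
        self.geometric_aug.validate()
        if self.contrast_filter_threshold < 0:
            raise ValueError("contrast filter threshold must be >= 0")


def window_and_normalize(image_hu: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Clip HU to [low, high] and map linearly onto [0, 1]."""
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"degenerate HU window ({lo}, {hi})")
    img = np.asarray(image_hu, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite HU values")
    return (np.clip(img, lo, hi) - lo) / (hi - lo)


def flip_point_to_point(image8: np.ndarray, foreground_mask: np.ndarray) -> np.ndarray:
    """Invert 8-bit intensities on the foreground; force background to 0.

    Each foreground pixel p maps to round((1 - p/255) * 255) = 255 - p;
    everything outside the foreground (outside the liver) is black.
    """
    img = np.asarray(image8)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("8-bit image values must lie in [0, 255]")
    fg = np.asarray(foreground_mask).astype(bool)
    if fg.shape != img.shape:
        raise ValueError("foreground mask must match image shape")
    out = np.zeros(img.shape, dtype=np.uint8)
    out[fg] = 255 - np.round(img[fg]).astype(np.int64)
    return out


def grayscale_float(image01: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random per-image contrast/brightness jitter on a [0,1] image.

    One multiplicative factor u ~ U(0.8, 1.2) and one additive offset
    v ~ U(-0.2, 0.2) per image, clipped back to [0, 1].
    """
    img = np.asarray(image01, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("grayscale_float expects a [0,1]-normalized image")
    u = rng.uniform(0.8, 1.2)
    v = rng.uniform(-0.2, 0.2)
    return np.clip(img * u + v, 0.0, 1.0)


@dataclass
class GeometricTransform:
    """A concrete sampled transform, applied jointly to image and masks."""

    angle_deg: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)
    mirror: bool = False
    shear: float = 0.0


def sample_transform(rng: np.random.Generator, config: GeometricAugConfig) -> GeometricTransform:
    return GeometricTransform(
        angle_deg=rng.uniform(-config.rotation_max_deg, config.rotation_max_deg),
        shift=(rng.uniform(-config.translation_max_px, config.translation_max_px),
               rng.uniform(-config.translation_max_px, config.translation_max_px)),
        mirror=bool(config.mirror and rng.integers(0, 2)),
        shear=rng.uniform(-config.shear_max, config.shear_max),
    )


def _apply_one(arr: np.ndarray, t: GeometricTransform, order: int) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if t.mirror:
        out = out[:, ::-1]
    if t.angle_deg % 90 == 0:
        out = np.rot90(out, int(round(t.angle_deg / 90)) % 4)
    elif t.angle_deg != 0:
        out = ndimage.rotate(out, t.angle_deg, reshape=False, order=order,
                             mode="constant", cval=0.0)
    if t.shear != 0:
        mat = np.array([[1.0, t.shear], [0.0, 1.0]])
        center = (np.asarray(out.shape) - 1) / 2.0
        out = ndimage.affine_transform(out, mat, offset=center - mat @ center,
                                       order=order, mode="constant", cval=0.0)
    if any(t.shift):
        out = ndimage.shift(out, t.shift, order=order, mode="constant", cval=0.0)
    return out


def apply_geometric(image: np.ndarray, masks: list[np.ndarray],
                    transform: GeometricTransform) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply one transform to the image (linear interp) and masks (nearest).

    Right-angle rotations and integer shifts are exact grid maps, so mask
    voxel counts are preserved there.
    """
    img = _apply_one(image, transform, order=1)
    out_masks = [_apply_one(m.astype(float), transform, order=0) > 0.5 for m in masks]
    return img, out_masks


def geometric_augment(image: np.ndarray, masks: list[np.ndarray],
                      rng: np.random.Generator,
                      config: GeometricAugConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sample one transform from `config` and apply it jointly."""
    config.validate()
    if (config.rotation_max_deg == 0 and config.translation_max_px == 0
            and not config.mirror and config.shear_max == 0):
        return image, masks
    return apply_geometric(image, masks, sample_transform(rng, config))


def slice_contrast(sample: SliceSample) -> float:
    """|mean HU in tumor - mean HU in liver-minus-tumor| for one slice."""
    tumor = sample.tumor_mask.astype(bool)
    liver_only = sample.liver_mask.astype(bool) & ~tumor
    if not tumor.any() or not liver_only.any():
        return np.inf
    return abs(float(sample.image[tumor].mean()) - float(sample.image[liver_only].mean()))


def contrast_filter(samples: list[SliceSample], threshold: float) -> list[SliceSample]:
    """Drop tumor-bearing slices whose liver/tumor contrast is below threshold.

    Slices without tumor pass unconditionally.  Intended for the training
    set only; validation and test sets are evaluated unfiltered.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = []
    for s in samples:
        if not s.liver_mask.any():
            raise ValueError(f"slice {s.case_id}:{s.slice_index} has an empty liver mask")
        if not s.tumor_mask.any() or slice_contrast(s) >= threshold:
            out.append(s)
    return out


def prepare_network_input(image_hu: np.ndarray, liver_mask: np.ndarray,
                          config: PreprocessConfig) -> np.ndarray:
    """The deterministic part of the pipeline: window -> 8-bit -> flip -> [0,1].

    Used identically at train and inference time; returns a [0,1] float
    image that is zero outside the liver when flipping is enabled.
    """
    config.validate()
    img01 = window_and_normalize(image_hu, config.hu_window)
    if not config.flip_enabled:
        return img01
    img8 = np.round(img01 * 255).astype(np.uint8)
    return flip_point_to_point(img8, liver_mask).astype(np.float64) / 255.0
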