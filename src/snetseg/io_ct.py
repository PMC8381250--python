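"""CT volume I/O, label conventions, slice extraction and cohort splits.

Volumes are stored as 3D arrays of Hounsfield units (HU) with the axial
direction along the *third* array axis.  Label volumes follow the LiTS
convention: 0 = background, 1 = liver, 2 = tumor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

LABEL_BACKGROUND = 0
LABEL_LIVER = 1
LABEL_TUMOR = 2


@dataclass
class CTVolume:
    """A 3D scalar field of HU values with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")


@dataclass
class SliceSample:
    """One axial slice: image plus liver and tumor masks."""

    image: np.ndarray
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    case_id: str
    slice_index: int

    def __post_init__(self):
        if not (self.image.shape == self.liver_mask.shape == self.tumor_mask.shape):
            raise ValueError("image and masks must share one shape")
        stray = self.tumor_mask.astype(bool) & ~self.liver_mask.astype(bool)
        if stray.any():
            raise ValueError("tumor mask extends outside the liver mask")


def read_volume(path) -> CTVolume:
    """Read a 3D NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(data=data, spacing=tuple(float(z) for z in zooms),
                    case_id=Path(path).name.split(".")[0])


def write_volume(vol: CTVolume, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def decode_labels(label_volume: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a LiTS label array into (liver_mask, tumor_mask).

    Liver includes tumor voxels (label >= 1); tumor is label == 2.
    """
    labels = np.asarray(label_volume)
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2])
    if bad.size:
        raise ValueError(f"invalid label value(s) {bad.tolist()}; expected 0/1/2")
    return labels >= LABEL_LIVER, labels == LABEL_TUMOR


def encode_labels(liver_mask: np.ndarray, tumor_mask: np.ndarray) -> np.ndarray:
    liver = np.asarray(liver_mask).astype(bool)
    tumor = np.asarray(tumor_mask).astype(bool)
    if (tumor & ~liver).any():
        raise ValueError("tumor mask extends outside the liver mask")
    labels = np.zeros(liver.shape, dtype=np.uint8)
    labels[liver] = LABEL_LIVER
    labels[tumor] = LABEL_TUMOR
    return labels


def extract_slices(case, keep_empty: bool = False) -> list[SliceSample]:
    """Turn a case (object with volume/liver_mask/tumor_mask) into 2D samples.

    Axial slices run along the third axis.  With ``keep_empty=False``,
    slices containing no liver voxels are dropped.
    """
    vol = case.volume
    liver = np.asarray(case.liver_mask).astype(bool)
    tumor = np.asarray(case.tumor_mask).astype(bool)
    if not (vol.data.shape == liver.shape == tumor.shape):
        raise ValueError("volume and masks must share one shape")
    out = []
    for k in range(vol.data.shape[2]):
        lv = liver[:, :, k]
        if not keep_empty and not lv.any():
            continue
        out.append(SliceSample(image=vol.data[:, :, k], liver_mask=lv,
                               tumor_mask=tumor[:, :, k],
                               case_id=vol.case_id, slice_index=k))
    return out


def split_cohort(case_ids: Sequence[str], fractions: tuple[float, float, float],
                 seed: int) -> tuple[list, list, list]:
    """Seed-reproducible case-level train/validation/test partition.

    Sizes follow largest-remainder rounding of ``fractions`` so they are
    disjoint, exhaustive and deterministic.  Raises if a stratum would
    be empty.
    """
    ids = list(case_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 cases to split")
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions must be 3 values summing to 1, got {fractions}")
    n = len(ids)
    raw = fr * n
    sizes = np.floor(raw).astype(int)
    rema = raw - sizes
    for i in np.argsort(-rema)[: n - sizes.sum()]:
        sizes[i] += 1
    if (sizes == 0).any():
        raise ValueError(f"empty stratum with fractions {fractions} and n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0]: sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return train, val, test


def save_split_manifest(path, train: Iterable, val: Iterable, test: Iterable) -> None:
    import pandas as pd

    rows = ([(c, "train") for c in train] + [(c, "val") for c in val]
            + [(c, "test") for c in test])
    pd.DataFrame(rows, columns=["case_id", "split"]).to_csv(path, index=False)
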