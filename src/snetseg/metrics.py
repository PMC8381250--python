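"""Segmentation evaluation metrics in the LiTS family.

Overlap metrics: Dice per case (DC, the unweighted mean of per-case
Dice scores), Dice global (DG, Dice on the pooled voxels of all cases)
and the volumetric overlap error (VOE = 1 - Jaccard).  Surface metrics:
average symmetric surface distance (ASSD) and root-mean-square
symmetric surface distance (RMSD), both in mm with anisotropic voxel
spacing.  A tumor-size stratification splits cases into small and large
groups at a configurable voxel-count cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


def _check_pair(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); both empty -> 1.0, exactly one empty -> 0.0."""
    a, b = _check_pair(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def voe(a, b) -> float:
    """Volumetric overlap error 1 - |A∩B|/|A∪B|; both empty -> 0."""
    a, b = _check_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return 1.0 - int((a & b).sum()) / union


def dice_per_case(cases: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """DC: unweighted mean of per-case Dice over (pred, ref) pairs."""
    if not cases:
        raise ValueError("empty cohort")
    return float(np.mean([dice(a, b) for a, b in cases]))


def dice_global(cases: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """DG: Dice on the concatenation of all cases' voxels."""
    if not cases:
        raise ValueError("empty cohort")
    inter = sum(int((np.asarray(a, bool) & np.asarray(b, bool)).sum())
                for a, b in cases)
    total = sum(int(np.asarray(a, bool).sum()) + int(np.asarray(b, bool).sum())
                for a, b in cases)
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one face-neighbour background voxel."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure, border_value=0)
    return mask & ~eroded


def surface_distances(a, b, spacing) -> tuple[float, float]:
    """(ASSD, RMSD) in mm between the boundaries of two nonempty masks.

    Boundaries use face connectivity; distances are Euclidean with the
    given per-axis spacing; both directed distance sets are pooled.
    """
    a, b = _check_pair(a, b)
    if not a.any() or not b.any():
        raise ValueError("surface distances need two nonempty masks")
    sp = np.asarray(spacing, dtype=float)
    if sp.shape != (a.ndim,) or (sp <= 0).any():
        raise ValueError(f"spacing must be {a.ndim} positive values")
    pa = np.argwhere(_boundary(a)) * sp
    pb = np.argwhere(_boundary(b)) * sp
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(pooled.mean()), float(np.sqrt((pooled ** 2).mean()))


def tumor_voxel_count(tumor_mask: np.ndarray) -> int:
    return int(np.asarray(tumor_mask).astype(bool).sum())


def stratify_by_size(counts: list[int], threshold: float = 0.2,
                     absolute: bool = False) -> list[str]:
    """Label each case 'small' or 'large' by tumor voxel count.

    By default the cutoff is ``threshold`` times the cohort's maximum
    per-case count (one cut line across the cohort); with
    ``absolute=True`` the threshold is a voxel count itself.  A count
    exactly at the cutoff is 'large'.
    """
    counts = [int(c) for c in counts]
    if not counts or max(counts) == 0:
        raise ValueError("cannot stratify a cohort with no tumor voxels")
    cutoff = float(threshold) if absolute else float(threshold) * max(counts)
    return ["large" if c >= cutoff else "small" for c in counts]


@dataclass
class EvalReport:
    """Per-case metric rows plus cohort-level aggregates."""

    per_case: pd.DataFrame
    cohort: dict
    strat_threshold: float

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)


def evaluate_cohort(predictions: dict, references: dict,
                    spacing=(1.0, 1.0, 2.5),
                    strat_threshold: float = 0.2,
                    strat_absolute: bool = False) -> EvalReport:
    """Full LiTS-style report over aligned {case_id: mask} dicts.

    Cases where a surface distance is undefined (either mask empty) get
    NaN there and are excluded from the cohort ASSD/RMSD means with a
    warning.
    """
    if set(predictions) != set(references):
        raise ValueError("prediction and reference case ids differ: "
                         f"{sorted(set(predictions) ^ set(references))}")
    ids = sorted(predictions)
    if not ids:
        raise ValueError("empty cohort")
    rows = []
    for cid in ids:
        pred = np.asarray(predictions[cid]).astype(bool)
        ref = np.asarray(references[cid]).astype(bool)
        try:
            assd, rmsd = surface_distances(pred, ref, spacing)
        except ValueError:
            assd = rmsd = np.nan
        rows.append({"case_id": cid,
                     "n_tumor_voxels": tumor_voxel_count(ref),
                     "DC": dice(pred, ref), "VOE": voe(pred, ref),
                     "ASSD_mm": assd, "RMSD_mm": rmsd})
    df = pd.DataFrame(rows)
    df["size_stratum"] = stratify_by_size(df["n_tumor_voxels"].tolist(),
                                          strat_threshold, strat_absolute)
    if df["ASSD_mm"].isna().any():
        warnings.warn("surface distances undefined for some cases "
                      "(empty mask); excluded from cohort means")
    pairs = [(predictions[c], references[c]) for c in ids]
    cohort = {
        "DC": dice_per_case(pairs),
        "DG": dice_global(pairs),
        "VOE_mean": float(df["VOE"].mean()),
        "ASSD_mean_mm": float(df["ASSD_mm"].mean()),
        "RMSD_mean_mm": float(df["RMSD_mm"].mean()),
    }
    for stratum in ("small", "large"):
        sub = df[df["size_stratum"] == stratum]
        if len(sub):
            sub_pairs = [(predictions[c], references[c]) for c in sub["case_id"]]
            cohort[f"DC_{stratum}"] = dice_per_case(sub_pairs)
            cohort[f"DG_{stratum}"] = dice_global(sub_pairs)
    return EvalReport(per_case=df, cohort=cohort, strat_threshold=strat_threshold)
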