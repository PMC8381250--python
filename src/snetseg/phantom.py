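"""Synthetic abdominal-CT phantom generator.

Emulates the intensity structure that makes liver-tumor segmentation
hard: an air background at about -1000 HU, a soft-tissue body ellipse,
an elliptical liver with one HU distribution, and blob-shaped tumors
drawn from a second, overlapping HU distribution.  Everything is a
deterministic function of (config, seed), so cohorts can be regenerated
anywhere without shipping data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_ct import CTVolume, encode_labels, write_volume


class PhantomPlacementError(RuntimeError):
    """Raised when tumors cannot be placed inside the liver."""


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the synthetic cohort.

    ``tumor_hu_mean`` defaults to ``liver_hu_mean - contrast_gap``; set it
    explicitly to override the gap.  HU values throughout.
    """

    image_size: int = 64
    n_slices: int = 10
    liver_hu_mean: float = 60.0
    liver_hu_sd: float = 10.0
    tumor_hu_mean: float | None = None
    tumor_hu_sd: float = 10.0
    body_hu_mean: float = 40.0
    background_hu: float = -1000.0
    tumor_count_range: tuple[int, int] = (1, 3)
    tumor_radius_range: tuple[int, int] = (3, 8)
    noise_sd: float = 5.0
    contrast_gap: float = 30.0
    liver_slice_fraction: float = 0.8
    seed: int = 0

    # liver ellipse semi-axes as a fraction of image_size
    _liver_axes: tuple[float, float] = (0.30, 0.25)
    _liver_center: tuple[float, float] = (0.50, 0.45)
    _body_axes: tuple[float, float] = (0.45, 0.42)

    def resolved_tumor_mean(self) -> float:
        if self.tumor_hu_mean is not None:
            return float(self.tumor_hu_mean)
        return float(self.liver_hu_mean - self.contrast_gap)

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.noise_sd < 0 or self.liver_hu_sd < 0 or self.tumor_hu_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for name in ("tumor_count_range", "tumor_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        if self.tumor_count_range[0] < 0 or self.tumor_radius_range[0] < 1:
            raise ValueError("tumor counts must be >= 0 and radii >= 1")
        semi_minor = min(self._liver_axes) * self.image_size
        if self.tumor_radius_range[1] >= semi_minor:
            raise ValueError(
                f"max tumor radius {self.tumor_radius_range[1]} must be smaller "
                f"than the liver semi-minor axis {semi_minor:.1f}")
        if not 0.0 < self.liver_slice_fraction <= 1.0:
            raise ValueError("liver_slice_fraction must be in (0, 1]")


@dataclass
class PhantomCase:
    """One generated case: HU volume plus liver and tumor masks."""

    volume: CTVolume
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.volume.data.shape == self.liver_mask.shape == self.tumor_mask.shape):
            raise ValueError("masks must match volume shape")
        if (self.tumor_mask & ~self.liver_mask).any():
            raise ValueError("tumor mask extends outside the liver mask")


def _ellipse_mask(n: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _disk(n: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _liver_slices(config: PhantomConfig) -> range:
    """Central contiguous run of slices that contain liver."""
    n_liver = max(1, round(config.liver_slice_fraction * config.n_slices))
    start = (config.n_slices - n_liver) // 2
    return range(start, start + n_liver)


def _tumor_blob(rng: np.random.Generator, n: int, cy: float, cx: float,
                r: float) -> np.ndarray:
    """Union of a base disk and 0-2 jittered satellite disks.

    Satellites stay within 0.4r of the centre with radius <= 0.7r, so the
    blob is contained in a disk of radius 1.1r — irregular borders with a
    bounded footprint.
    """
    blob = _disk(n, cy, cx, r)
    for _ in range(rng.integers(0, 3)):
        ang = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.4 * r)
        rr = rng.uniform(0.5 * r, 0.7 * r)
        blob |= _disk(n, cy + rho * np.sin(ang), cx + rho * np.cos(ang), rr)
    return blob


def generate_case(config: PhantomConfig, seed: int) -> PhantomCase:
    """Generate one phantom case deterministically from (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n, nz = config.image_size, config.n_slices
    liver = np.zeros((n, n, nz), dtype=bool)
    tumor = np.zeros((n, n, nz), dtype=bool)

    cy, cx = (c * n for c in config._liver_center)
    ay, ax = (a * n for a in config._liver_axes)
    body = _ellipse_mask(n, 0.5 * n, 0.5 * n, config._body_axes[0] * n,
                         config._body_axes[1] * n)

    liver_ks = _liver_slices(config)
    for k in liver_ks:
        # mild through-plane tapering keeps each slice's liver an ellipse
        t = (k - liver_ks.start + 0.5) / len(liver_ks)
        scale = 0.85 + 0.15 * np.sin(np.pi * t)
        liver[:, :, k] = _ellipse_mask(n, cy, cx, ay * scale, ax * scale)

    n_tumors = int(rng.integers(config.tumor_count_range[0],
                                config.tumor_count_range[1] + 1))
    for _ in range(n_tumors):
        r = float(rng.integers(config.tumor_radius_range[0],
                               config.tumor_radius_range[1] + 1))
        placed = False
        for _attempt in range(100):
            k0 = int(rng.choice(list(liver_ks)))
            span = int(rng.integers(1, min(3, len(liver_ks)) + 1))
            ks = [k for k in range(k0, k0 + span) if k in liver_ks]
            ty = rng.uniform(cy - ay, cy + ay)
            tx = rng.uniform(cx - ax, cx + ax)
            blob2d = {}
            ok = True
            for i, k in enumerate(ks):
                rk = r * np.sqrt(max(1.0 - (i / max(len(ks), 1)) ** 2, 0.25))
                b = _tumor_blob(rng, n, ty, tx, rk)
                if not b.any() or (b & ~liver[:, :, k]).any():
                    ok = False
                    break
                blob2d[k] = b
            if ok:
                for k, b in blob2d.items():
                    tumor[:, :, k] |= b
                placed = True
                break
        if not placed:
            raise PhantomPlacementError(
                f"could not place a radius-{r:.0f} tumor inside the liver "
                "after 100 attempts; widen the liver or shrink the tumors")

    tumor_mean = config.resolved_tumor_mean()
    vol = np.full((n, n, nz), config.background_hu, dtype=np.float32)
    body3d = np.broadcast_to(body[:, :, None], vol.shape)
    vol[body3d] = config.body_hu_mean + rng.normal(0, 5.0, int(body3d.sum()))
    vol[liver] = config.liver_hu_mean + rng.normal(0, config.liver_hu_sd,
                                                   int(liver.sum()))
    vol[tumor] = tumor_mean + rng.normal(0, config.tumor_hu_sd, int(tumor.sum()))
    vol += rng.normal(0, config.noise_sd, vol.shape).astype(np.float32)

    case_id = f"phantom-{seed:08d}"
    volume = CTVolume(data=vol, spacing=(1.0, 1.0, 2.5), case_id=case_id)
    return PhantomCase(volume=volume, liver_mask=liver, tumor_mask=tumor,
                       provenance={"config": dataclasses.asdict(config),
                                   "seed": int(seed)})


def _case_seed(master_seed: int, index: int) -> int:
    # counter-based derivation: independent of generation order
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2 ** 31))


def generate_cohort(config: PhantomConfig, n_cases: int, seed: int) -> list[PhantomCase]:
    """Generate a cohort with tumor sizes spread across the radius range.

    Case ``i`` gets a pinned base radius from an even grid over
    ``tumor_radius_range`` so both small- and large-tumor strata are
    populated; per-case seeds derive from the master seed by counter.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    config.validate()
    lo, hi = config.tumor_radius_range
    radii = np.round(np.linspace(lo, hi, n_cases)).astype(int)
    cases = []
    for i in range(n_cases):
        cfg_i = dataclasses.replace(config,
                                    tumor_radius_range=(int(radii[i]), int(radii[i])))
        case = generate_case(cfg_i, _case_seed(seed, i))
        case.volume.case_id = f"phantom-{i:03d}"
        cases.append(case)
    return cases


def save_cohort(cases: list[PhantomCase], out_dir) -> None:
    """Write each case as NIfTI volume + labels plus a CSV manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        cid = case.volume.case_id
        write_volume(case.volume, out / f"{cid}_volume.nii.gz")
        labels = encode_labels(case.liver_mask, case.tumor_mask)
        write_volume(CTVolume(labels, case.volume.spacing, cid),
                     out / f"{cid}_labels.nii.gz")
        rows.append({"case_id": cid,
                     "n_tumor_voxels": int(case.tumor_mask.sum()),
                     "seed": case.provenance.get("seed")})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
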