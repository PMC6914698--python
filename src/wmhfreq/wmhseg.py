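"""Threshold-based WMH segmentation and lesion summary measures.

A FLAIR volume is z-scored over brain voxels and every brain voxel whose
normalized intensity is at least ``k`` standard deviations above the brain
mean (default k = 1.2, inclusive) is labeled a white matter hyperintensity
(WMH). Normal-appearing white matter (NAWM) is the exact set difference
white_matter \\ WMH. Statistics (mean and SD) are computed over brain voxels
only: background zeros would otherwise drag the mean down and invalidate the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaskSet", "LesionStats", "EmptyMaskError", "DegenerateImageError",
    "normalize_intensity", "segment_wmh", "derive_nawm",
    "lesion_volume", "mean_fa_in_mask", "dice", "compute_lesion_stats",
]


class DegenerateImageError(ValueError):
    """Brain intensity SD is zero; the threshold rule would flag everything."""


class EmptyMaskError(ValueError):
    """A mean was requested over an empty mask."""


@dataclass
class MaskSet:
    """Per-subject binary masks on the common grid."""

    brain: np.ndarray
    white_matter: np.ndarray
    wmh: np.ndarray
    nawm: np.ndarray
    voxel_size_mm: tuple

    def __post_init__(self):
        if np.any(self.wmh & ~self.brain):
            raise ValueError("wmh mask extends outside the brain")
        if np.any(self.nawm & self.wmh):
            raise ValueError("nawm and wmh overlap")


@dataclass
class LesionStats:
    """Scalar lesion summaries for one subject."""

    wmh_volume_cm3: float
    mean_fa_wmh: float    # NaN when the WMH mask is empty
    mean_fa_nawm: float


def normalize_intensity(flair: np.ndarray, brain: np.ndarray) -> np.ndarray:
    """Z-score the image over brain voxels; NaN outside the brain.

    Invariant to any affine rescaling a*x + c (a > 0) of the input.
    """
    brain = np.asarray(brain, bool)
    if not brain.any():
        raise ValueError("brain mask is empty")
    vals = np.asarray(flair, float)[brain]
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise DegenerateImageError("brain intensities are constant (SD = 0)")
    out = np.full(np.shape(flair), np.nan)
    out[brain] = (np.asarray(flair, float)[brain] - mu) / sd
    return out


def segment_wmh(flair_norm: np.ndarray, brain: np.ndarray, k: float = 1.2) -> np.ndarray:
    """WMH mask: brain voxels with normalized intensity >= k (inclusive)."""
    brain = np.asarray(brain, bool)
    with np.errstate(invalid="ignore"):
        return brain & (np.asarray(flair_norm, float) >= k)


def derive_nawm(white_matter: np.ndarray, wmh: np.ndarray) -> np.ndarray:
    """NAWM = white_matter \\ wmh, exact voxelwise set difference."""
    white_matter = np.asarray(white_matter, bool)
    wmh = np.asarray(wmh, bool)
    if white_matter.shape != wmh.shape:
        raise ValueError(
            f"grid mismatch: white matter {white_matter.shape} vs wmh {wmh.shape}")
    return white_matter & ~wmh


def lesion_volume(mask: np.ndarray, voxel_size_mm) -> float:
    """Mask volume in cm^3: positive-voxel count times voxel volume / 1000."""
    vs = np.asarray(voxel_size_mm, float)
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    return float(np.count_nonzero(mask) * np.prod(vs) / 1000.0)


def mean_fa_in_mask(fa: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean FA over mask voxels; raises on an empty mask."""
    mask = np.asarray(mask, bool)
    n = np.count_nonzero(mask)
    if n == 0:
        raise EmptyMaskError("mean requested over an empty mask")
    vals = np.asarray(fa, float)[mask]
    if np.any(np.isnan(vals)):
        raise ValueError("mask includes voxels where FA is undefined")
    return float(vals.mean())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 1.0 for two empty masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)


def compute_lesion_stats(fa: np.ndarray, masks: MaskSet) -> LesionStats:
    """Per-subject lesion volume and mean FA in WMH / NAWM.

    An empty WMH mask yields NaN mean FA (the subject has no lesion voxels),
    never a silent zero.
    """
    vol = lesion_volume(masks.wmh, masks.voxel_size_mm)
    try:
        fa_wmh = mean_fa_in_mask(fa, masks.wmh)
    except EmptyMaskError:
        fa_wmh = float("nan")
    try:
        fa_nawm = mean_fa_in_mask(fa, masks.nawm)
    except EmptyMaskError:
        fa_nawm = float("nan")
    return LesionStats(wmh_volume_cm3=vol, mean_fa_wmh=fa_wmh, mean_fa_nawm=fa_nawm)
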