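"""Voxelwise WMH frequency mapping and frequency binning.

The frequency map records, per voxel, the fraction of cohort subjects whose
WMH mask is positive there (55 positives out of 557 subjects -> 55/557 =
9.9%). Voxels are stratified into half-open percentage intervals
(low, high] — by default (0,5], (5,10], (10,15], (15,20] — evaluated on the
exact rational value 100*count/n (never on pre-rounded percentages), so a
voxel with zero frequency belongs to no bin and boundary frequencies land
deterministically in the lower-labeled bin. Frequencies above the top edge
are left unbinned unless an overflow bin is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyMap", "FrequencyBins", "EmptyBinError", "DEFAULT_EDGES_PERCENT",
    "build_frequency_map", "bin_frequency_map", "bin_voxel_counts",
    "normative_fa_by_bin",
]

#: default stratification, in percent: (0,5], (5,10], (10,15], (15,20]
DEFAULT_EDGES_PERCENT = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0))


class EmptyBinError(ValueError):
    """A frequency bin contains no voxels."""


@dataclass
class FrequencyMap:
    """Voxelwise positive counts over a cohort; frequencies are counts/n."""

    counts: np.ndarray      # integer, per voxel
    n_subjects: int
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    @property
    def f(self) -> np.ndarray:
        """Fraction of subjects positive per voxel, in [0, 1]."""
        return self.counts / self.n_subjects


@dataclass
class FrequencyBins:
    """Disjoint voxel strata by WMH frequency interval."""

    edges_percent: tuple            # ((low, high], ...) in percent
    bin_masks: list                 # one boolean mask per interval
    labels: list

    def __len__(self):
        return len(self.bin_masks)


def build_frequency_map(masks, voxel_size_mm=(1.0, 1.0, 1.0)) -> FrequencyMap:
    """Average binary WMH masks over subjects into a frequency map."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    shape = np.shape(masks[0])
    counts = np.zeros(shape, dtype=np.int64)
    for i, m in enumerate(masks):
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError(f"mask {i} grid {m.shape} differs from {shape}")
        counts += m.astype(bool)
    return FrequencyMap(counts=counts, n_subjects=len(masks),
                        voxel_size_mm=tuple(voxel_size_mm))


def bin_frequency_map(freq: FrequencyMap, edges_percent=DEFAULT_EDGES_PERCENT,
                      overflow: bool = False) -> FrequencyBins:
    """Assign voxels to half-open (low, high] percentage intervals.

    Comparison is on the exact rational 100*count/n, implemented in integer
    arithmetic (100*count vs edge*n) so no floating-point rounding can move a
    boundary voxel. With ``overflow`` a final bin (top, 100] collects voxels
    above the last edge.
    """
    edges = [tuple(map(float, e)) for e in edges_percent]
    for lo, hi in edges:
        if not lo < hi:
            raise ValueError(f"bad interval ({lo}, {hi}]")
    for (_, hi0), (lo1, _) in zip(edges, edges[1:]):
        if lo1 < hi0:
            raise ValueError("overlapping intervals")
    if overflow:
        edges.append((edges[-1][1], 100.0))
    pct_times_n = 100.0 * freq.counts          # compare against edge * n: exact
    n = freq.n_subjects
    bin_masks, labels = [], []
    for lo, hi in edges:
        m = (pct_times_n > lo * n) & (pct_times_n <= hi * n)
        bin_masks.append(m)
        labels.append(f"{lo:g}%-{hi:g}%")
    return FrequencyBins(edges_percent=tuple(edges), bin_masks=bin_masks, labels=labels)


def bin_voxel_counts(bins: FrequencyBins) -> pd.Series:
    """Voxel count per bin, labeled by interval."""
    return pd.Series([int(np.count_nonzero(m)) for m in bins.bin_masks],
                     index=bins.labels, name="n_voxels")


def normative_fa_by_bin(fa_maps, bins: FrequencyBins) -> pd.DataFrame:
    """Per-subject mean FA within each frequency bin (subjects x bins).

    Every bin must be non-empty; an :class:`EmptyBinError` names the offending
    bins. FA maps must be defined (non-NaN) over every binned voxel.
    """
    empty = [lab for lab, m in zip(bins.labels, bins.bin_masks)
             if not np.any(m)]
    if empty:
        raise EmptyBinError(f"empty frequency bins: {empty}")
    rows = []
    for fa in fa_maps:
        fa = np.asarray(fa, float)
        row = []
        for m in bins.bin_masks:
            vals = fa[m]
            if np.any(np.isnan(vals)):
                raise ValueError("bin includes voxels where FA is undefined")
            row.append(vals.mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=bins.labels)
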