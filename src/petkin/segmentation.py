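"""Segmentation of dynamic images into kinetically homogeneous segments.

The first stage of residue mapping reduces the voxel-level dataset to a
small set of segments whose member time courses are each approximately
proportional to the segment mean.  A recursive binary splitting scheme is
used: the segment whose members deviate most from proportionality (largest
mean correlation distance between L1-normalised curves) is split in two by
average-linkage hierarchical clustering, until either the target number of
segments is reached or every segment satisfies the proportionality
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["ReducedDataset", "segment_image"]

#: relative floor applied to segment standard deviations (fraction of the
#: segment-mean peak) so weights 1/sigma^2 stay finite
SD_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class ReducedDataset:
    """Segment-level reduction of a dynamic image."""

    means: np.ndarray       # (S, N_T) segment mean curves
    sds: np.ndarray         # (S, N_T) per-frame standard deviations (floored)
    sizes: np.ndarray       # (S,) voxels per segment
    labels: np.ndarray      # (n_vox,) voxel -> segment index

    @property
    def n_segments(self) -> int:
        return self.means.shape[0]

    @property
    def n_frames(self) -> int:
        return self.means.shape[1]


def _l1_normalise(curves: np.ndarray) -> np.ndarray:
    norm = np.sum(np.abs(curves), axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return curves / norm


def _corr_distance_to_mean(normed: np.ndarray) -> float:
    """Mean (1 - Pearson r) of member curves against their mean curve."""
    mean = normed.mean(axis=0)
    mc = mean - mean.mean()
    ms = np.sqrt(np.sum(mc ** 2))
    xc = normed - normed.mean(axis=1, keepdims=True)
    xs = np.sqrt(np.sum(xc ** 2, axis=1))
    ok = (xs > 1e-15) & (ms > 1e-15)
    r = np.ones(normed.shape[0])
    if ms > 1e-15:
        r[ok] = (xc[ok] @ mc) / (xs[ok] * ms)
    return float(np.mean(1.0 - r))


def _split_two(normed: np.ndarray) -> np.ndarray:
    """Binary split by Ward clustering of the normalised curves.

    Ward linkage yields balanced shape-driven splits; average linkage on
    correlation distance tends to peel single outliers instead.
    """
    Z = linkage(normed, method="ward")
    grp = fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(grp)) < 2:  # all identical: arbitrary balanced split
        grp = np.ones(normed.shape[0], dtype=int)
        grp[: normed.shape[0] // 2] = 2
    return grp


def segment_image(dynamic_image: np.ndarray, s_target: int = 100,
                  min_segment_size: int = 1,
                  proportionality_tol: float = 1e-4,
                  metric_curves: Optional[np.ndarray] = None) -> ReducedDataset:
    """Partition voxel time courses into proportionality segments.

    Parameters
    ----------
    dynamic_image : (n_vox, N_T) array
        Voxel time-course data (any spatial layout, flattened).
    s_target : int
        Ceiling on the number of segments.
    min_segment_size : int
        Segments smaller than twice this are never split.
    proportionality_tol : float
        Stop splitting a segment once the mean correlation distance of its
        members to the segment mean falls below this.
    metric_curves : (n_vox, n_features) array, optional
        Curves used for the clustering metric only (e.g. temporally rebinned
        or otherwise denoised data); segment means and SDs are always
        computed from ``dynamic_image``.
    """
    z = np.asarray(dynamic_image, dtype=float)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ValueError("dynamic image must be a (n_vox, N_T) array")
    n_vox = z.shape[0]
    if s_target < 1:
        raise ValueError("s_target must be >= 1")
    if s_target > n_vox:
        raise ValueError("cannot request more segments than voxels")
    metric = z if metric_curves is None else np.asarray(metric_curves, float)
    if metric.shape[0] != n_vox:
        raise ValueError("metric_curves must have one row per voxel")
    normed = _l1_normalise(metric)

    segments = [np.arange(n_vox)]
    scores = [_corr_distance_to_mean(normed)]
    while len(segments) < s_target:
        worst = int(np.argmax(scores))
        if scores[worst] <= proportionality_tol:
            break
        idx = segments[worst]
        if idx.size < max(2, 2 * min_segment_size):
            scores[worst] = -np.inf  # unsplittable; look elsewhere
            if np.all(np.isneginf(scores)):
                break
            continue
        grp = _split_two(normed[idx])
        a, b = idx[grp == 1], idx[grp == 2]
        if a.size == 0 or b.size == 0:
            scores[worst] = -np.inf
            if np.all(np.isneginf(scores)):
                break
            continue
        segments[worst] = a
        scores[worst] = _corr_distance_to_mean(normed[a])
        segments.append(b)
        scores.append(_corr_distance_to_mean(normed[b]))

    labels = np.empty(n_vox, dtype=int)
    means, sds, sizes = [], [], []
    for s, idx in enumerate(segments):
        labels[idx] = s
        seg = z[idx]
        mean = seg.mean(axis=0)
        # uncertainty attached to the segment MEAN curve: sd / sqrt(n);
        # the floor is a fraction of the segment peak per member voxel, so
        # it scales down with pooling and preserves the frame weighting
        sd = seg.std(axis=0, ddof=1) / np.sqrt(idx.size) if idx.size > 1 \
            else np.zeros_like(mean)
        floor = SD_FLOOR_FRACTION * max(float(np.max(np.abs(mean))), 1e-12) \
            / np.sqrt(idx.size)
        sds.append(np.maximum(sd, floor))
        means.append(mean)
        sizes.append(idx.size)
    return ReducedDataset(np.asarray(means), np.asarray(sds),
                          np.asarray(sizes), labels)
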