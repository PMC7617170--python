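"""Segmentation quality and consistency metrics."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = ["dice", "directed_hausdorff", "cov"]


def dice(seg_a: np.ndarray, seg_b: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Per-class Dice overlap 2|A n B| / (|A| + |B|) of two hard label maps.

    Empty-vs-empty is defined as 1.
    """
    seg_a = np.asarray(seg_a)
    seg_b = np.asarray(seg_b)
    if seg_a.shape != seg_b.shape:
        raise ValueError(f"shape mismatch: {seg_a.shape} vs {seg_b.shape}")
    out = np.empty(n_classes)
    for k in range(n_classes):
        a = seg_a == k
        b = seg_b == k
        denom = a.sum() + b.sum()
        out[k] = 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom
    return out


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~binary_erosion(mask)


def directed_hausdorff(
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    n_classes: int = 4,
) -> np.ndarray:
    """Per-class directed Hausdorff distance (mm) from A's surface to B.

    max over surface voxels of A of the distance to the nearest voxel of
    B.  An empty class mask on either side yields inf with a warning.
    """
    seg_a = np.asarray(seg_a)
    seg_b = np.asarray(seg_b)
    if seg_a.shape != seg_b.shape:
        raise ValueError(f"shape mismatch: {seg_a.shape} vs {seg_b.shape}")
    spacing = np.asarray(spacing, dtype=np.float64)
    out = np.empty(n_classes)
    for k in range(n_classes):
        a = seg_a == k
        b = seg_b == k
        if not a.any() or not b.any():
            warnings.warn(f"empty mask for class {k}; Hausdorff set to inf")
            out[k] = np.inf
            continue
        pa = np.argwhere(_surface(a)) * spacing
        pb = np.argwhere(b) * spacing
        d, _ = cKDTree(pb).query(pa)
        out[k] = float(d.max())
    return out


def cov(volumes) -> float:
    """Coefficient of variation: sample (n-1) sd over mean."""
    v = np.asarray(volumes, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CoV needs at least 2 volumes")
    m = v.mean()
    if m == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(v.std(ddof=1) / m)
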