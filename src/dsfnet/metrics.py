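"""Overlap and surface-distance evaluation metrics.

DSC reflects accuracy inside the target region; ASSD (in mm) reflects
accuracy of the target boundary. Surfaces are the foreground voxels with at
least one face-adjacent background neighbour (6-connectivity in 3-D,
4-connectivity in 2-D; voxels on the array border count as surface). ASSD is
the pooled mean over the union of both directed surface-distance sets,
computed with a Euclidean distance transform honouring the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["LabeledVolume", "dsc", "extract_surface", "assd"]


@dataclass
class LabeledVolume:
    """A binary mask with physical voxel spacing in mm."""

    mask: np.ndarray
    spacing: tuple = field(default=None)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask must be binary")
        if self.spacing is None:
            self.spacing = (1.0,) * self.mask.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.mask.ndim:
            raise ValueError("spacing must have one entry per mask axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


def _as_mask(v) -> np.ndarray:
    m = v.mask if isinstance(v, LabeledVolume) else np.asarray(v)
    if not np.all((m == 0) | (m == 1)):
        raise ValueError("mask must be binary")
    return m.astype(bool)


def dsc(pred, truth) -> float:
    """Dice Similarity Coefficient 2|P & T| / (|P| + |T|); 1.0 if both empty."""
    p, t = _as_mask(pred), _as_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background neighbour."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def extract_surface(v) -> np.ndarray:
    """Boundary-voxel coordinates in mm, shape (n_points, ndim)."""
    if isinstance(v, LabeledVolume):
        mask, spacing = v.mask.astype(bool), np.asarray(v.spacing)
    else:
        mask = _as_mask(v)
        spacing = np.ones(mask.ndim)
    pts = np.argwhere(_surface_mask(mask))
    return pts * spacing


def assd(pred, truth, spacing=None) -> float:
    """Average Symmetric Surface Distance in mm.

    Pooled mean of the directed distances from each surface voxel of one mask
    to the nearest surface voxel of the other, both directions.
    """
    if isinstance(pred, LabeledVolume) and isinstance(truth, LabeledVolume):
        if pred.spacing != truth.spacing:
            raise ValueError("pred and truth must share voxel spacing")
        spacing = pred.spacing
    p, t = _as_mask(pred), _as_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        raise ValueError("assd is undefined for an empty mask")
    spacing = np.ones(p.ndim) if spacing is None else np.asarray(spacing, float)
    sp, st = _surface_mask(p), _surface_mask(t)
    # distance map to the *other* surface, sampled at this surface's voxels
    d_to_t = ndimage.distance_transform_edt(~st, sampling=spacing)
    d_to_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    dists = np.concatenate([d_to_t[sp], d_to_p[st]])
    return float(dists.mean())
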