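"""CBCT preprocessing pipeline.

Standardizes raw scans for training: isotropic resampling to 0.4 mm,
intensity clipping to [0, 2500] (suppressing metal-artifact extremes),
division by 2500 to [0, 1], collapse of instance labels to a binary
tooth/background mask, axial slicing with center crop/pad to 224 x 224, and a
deterministic 6:2:2 train/validation/test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "SplitManifest",
    "load_volume",
    "save_volume",
    "resample",
    "clip_normalize",
    "binarize_labels",
    "make_slices",
    "reassemble",
    "split",
    "CLIP_MAX",
    "TARGET_SPACING",
]

CLIP_MAX = 2500.0
TARGET_SPACING = 0.4  # mm
SLICE_SIZE = 224


@dataclass
class Volume:
    """A 3-D scalar field with voxel spacing (mm) and an affine."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asanyarray(img.dataobj).astype(np.float32), spacing,
                  img.affine.copy())


def save_volume(v: Volume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data), v.affine), str(path))


def _rescaled_affine(affine: np.ndarray, factors: np.ndarray) -> np.ndarray:
    out = affine.copy()
    out[:3, :3] = affine[:3, :3] / factors[np.newaxis, :]
    return out


def resample(v: Volume, target_spacing: float = TARGET_SPACING,
             is_label: bool = False) -> Volume:
    """Resample to isotropic ``target_spacing`` (trilinear for intensities,
    nearest-neighbour for label volumes)."""
    if target_spacing <= 0:
        raise ValueError("target spacing must be > 0")
    factors = np.asarray(v.spacing) / target_spacing
    if np.allclose(factors, 1.0):
        return Volume(v.data.copy(), (target_spacing,) * 3, v.affine.copy())
    order = 0 if is_label else 1
    out = ndimage.zoom(v.data.astype(np.float32), factors, order=order,
                       mode="nearest", grid_mode=True)
    if is_label:
        out = out.astype(v.data.dtype)
    return Volume(out, (target_spacing,) * 3, _rescaled_affine(v.affine, factors))


def clip_normalize(v: Volume, clip_max: float = CLIP_MAX) -> Volume:
    """Clip to [0, clip_max] and divide by clip_max -> intensities in [0, 1]."""
    out = np.clip(v.data, 0.0, clip_max) / clip_max
    return Volume(out.astype(np.float32), v.spacing, v.affine.copy())


def binarize_labels(labels: Volume) -> Volume:
    """Collapse instance labels: 0 stays background, any positive id -> 1."""
    data = labels.data
    if np.any(data < 0):
        raise ValueError("labels must be non-negative")
    return Volume((data > 0).astype(np.uint8), labels.spacing, labels.affine.copy())


def _crop_pad_2d(sl: np.ndarray, size: int) -> tuple[np.ndarray, dict]:
    """Center crop / symmetric zero-pad a 2-D slice to (size, size)."""
    h, w = sl.shape
    meta = {"orig": (h, w)}
    out = sl
    crop = []
    for ax, n in enumerate((h, w)):
        if n > size:
            lo = (n - size) // 2
            crop.append((lo, lo + size))
        else:
            crop.append((0, n))
    out = out[crop[0][0]: crop[0][1], crop[1][0]: crop[1][1]]
    pads = []
    for n in out.shape:
        total = size - n
        pads.append((total // 2, total - total // 2))
    out = np.pad(out, pads)
    meta["crop"] = crop
    meta["pad"] = pads
    return out, meta


def make_slices(v: Volume, masks: Volume | None = None, size: int = SLICE_SIZE):
    """Split a preprocessed volume into axial (last-axis) 2-D samples.

    Returns ``(images, mask_slices, meta)`` where images has shape
    (Z, size, size) and ``meta`` carries the geometry needed by
    :func:`reassemble`.
    """
    if masks is not None and masks.data.shape != v.data.shape:
        raise ValueError("image and mask volumes must share shape")
    z = v.data.shape[2]
    imgs = np.empty((z, size, size), dtype=np.float32)
    msk = np.empty((z, size, size), dtype=np.uint8) if masks is not None else None
    meta = None
    for k in range(z):
        imgs[k], meta = _crop_pad_2d(v.data[:, :, k].astype(np.float32), size)
        if masks is not None:
            msk[k], _ = _crop_pad_2d(masks.data[:, :, k], size)
    meta = dict(meta or {"orig": v.data.shape[:2], "crop": None, "pad": None})
    meta["n_slices"] = z
    meta["size"] = size
    meta["spacing"] = v.spacing
    return imgs, msk, meta


def reassemble(slices: np.ndarray, meta: dict) -> np.ndarray:
    """Invert :func:`make_slices` geometry: (Z, size, size) -> (H, W, Z).

    Cropped-away margins (in-plane size > ``size``) are filled with zeros.
    """
    h, w = meta["orig"]
    z = meta["n_slices"]
    (ph, _), (pw, _) = meta["pad"]
    (ch0, ch1), (cw0, cw1) = meta["crop"]
    out = np.zeros((h, w, z), dtype=slices.dtype)
    inner_h, inner_w = ch1 - ch0, cw1 - cw0
    for k in range(z):
        core = slices[k][ph: ph + inner_h, pw: pw + inner_w]
        out[ch0:ch1, cw0:cw1, k] = core
    return out


@dataclass
class SplitManifest:
    train: list
    val: list
    test: list
    seed: int

    def to_dict(self):
        return {"train": self.train, "val": self.val, "test": self.test,
                "seed": self.seed}

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["val"], d["test"], d["seed"])


def split(ids, seed: int) -> SplitManifest:
    """Deterministic shuffled 6:2:2 split (floor/floor/remainder)."""
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 ids for a 6:2:2 split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = int(np.floor(0.6 * n))
    n_val = int(np.floor(0.2 * n))
    return SplitManifest(
        train=shuffled[:n_train],
        val=shuffled[n_train: n_train + n_val],
        test=shuffled[n_train + n_val:],
        seed=seed,
    )
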