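"""Synthetic CBCT-like tooth phantoms.

Real oral CBCT is hard to segment for two structural reasons: tooth contours
are blurred by acquisition physics, and roots occupy far fewer pixels than
crowns (scale imbalance). The generator reproduces exactly those two failure
modes on an axial-slice phantom: an arch of bright elliptical "crowns" with
thin, tapering, lower-contrast "roots" over a smooth bone band, blurred with
a Gaussian, plus additive noise and optional bright streaks (a stand-in for
metal artifacts). Raw intensities live on the [0, 2500] scale the
preprocessing pipeline expects.

Every sample is deterministic given ``(spec.seed, index)``. The ground-truth
mask is the *pre-blur* geometry; a ``difficulty_map`` flags root pixels
(bit 1) and a boundary band around the contour (bit 2) for stratified
reporting on difficult-to-segment regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocessing import Volume, save_volume

__all__ = ["PhantomSpec", "PhantomSample", "generate_slice", "generate_dataset"]

ROOT_FLAG = 1
BOUNDARY_FLAG = 2


@dataclass
class PhantomSpec:
    """Parametric description of a phantom slice (pixel units at 224 x 224)."""

    image_size: int = 224
    n_teeth: int = 6
    crown_radius_range: tuple = (8.0, 13.0)
    root_length_range: tuple = (16.0, 28.0)
    root_width_range: tuple = (2.5, 5.0)
    boundary_blur_sigma: float = 1.5
    noise_sd: float = 40.0
    streak_artifact_prob: float = 0.3
    crown_intensity: float = 2200.0
    root_intensity: float = 1500.0
    bone_intensity: float = 900.0
    background_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if max(self.root_width_range) >= min(self.crown_radius_range):
            raise ValueError(
                "root width must be smaller than crown radius "
                "(the crown/root scale imbalance is the point of the phantom)"
            )
        if self.boundary_blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur sigma and noise sd must be >= 0")
        for v in (self.crown_intensity, self.root_intensity,
                  self.bone_intensity, self.background_intensity):
            if not 0.0 <= v <= 2500.0:
                raise ValueError("intensities must lie in [0, 2500]")
        if self.n_teeth < 1:
            raise ValueError("need at least one tooth")

    def scaled(self, image_size: int) -> "PhantomSpec":
        """The same phantom geometry at a different resolution."""
        f = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            crown_radius_range=tuple(r * f for r in self.crown_radius_range),
            root_length_range=tuple(r * f for r in self.root_length_range),
            root_width_range=tuple(r * f for r in self.root_width_range),
            boundary_blur_sigma=self.boundary_blur_sigma * f,
        )


@dataclass
class PhantomSample:
    image: np.ndarray          # raw intensities in [0, 2500]
    mask: np.ndarray           # binary ground truth (pre-blur geometry)
    difficulty_map: np.ndarray # uint8 bitmask: 1 = root, 2 = boundary band
    crown_mask: np.ndarray = field(repr=False, default=None)
    root_mask: np.ndarray = field(repr=False, default=None)


def _rng_for(spec: PhantomSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, int(index)]))


def generate_slice(spec: PhantomSpec, index: int = 0) -> PhantomSample:
    """Render one phantom slice, deterministic in ``(spec.seed, index)``."""
    s = spec.image_size
    rng = _rng_for(spec, index)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # dental arch: arc of a circle in the lower half of the image
    arch_cx, arch_cy = s / 2.0, 0.72 * s
    arch_r = 0.32 * s
    angles = np.linspace(np.pi * 1.18, np.pi * 1.82, spec.n_teeth)
    angles = angles + rng.uniform(-0.02, 0.02, spec.n_teeth) * np.pi

    crown = np.zeros((s, s), dtype=bool)
    root = np.zeros((s, s), dtype=bool)
    crown_centers = []
    for a in angles:
        cx = arch_cx + arch_r * np.cos(a)
        cy = arch_cy + arch_r * np.sin(a)
        r = rng.uniform(*spec.crown_radius_range)
        if not (r < cx < s - r and r < cy < s - r):
            raise ValueError("phantom geometry does not fit in the image")
        crown_centers.append((cx, cy))
        elong = rng.uniform(1.0, 1.3)
        crown |= ((xx - cx) / r) ** 2 + ((yy - cy) / (r * elong)) ** 2 <= 1.0

        # root: tapering band from the crown center away from the arch center
        ux, uy = np.cos(a), np.sin(a)          # outward radial direction
        length = rng.uniform(*spec.root_length_range)
        width = rng.uniform(*spec.root_width_range)
        # coordinates along (t) and across (d) the root axis
        t = (xx - cx) * ux + (yy - cy) * uy
        d = -(xx - cx) * uy + (yy - cy) * ux
        frac = t / length
        taper = width * (1.0 - 0.8 * frac)      # tip ~20% of base width
        root |= (frac >= 0.0) & (frac <= 1.0) & (np.abs(d) <= taper / 2.0)
    root &= ~crown
    mask = crown | root

    # smooth bone band following the arch
    dist_to_arch = np.abs(np.hypot(xx - arch_cx, yy - arch_cy) - arch_r)
    bone = dist_to_arch <= 0.12 * s
    bone_field = ndimage.gaussian_filter(bone.astype(np.float64), 0.02 * s)

    img = np.full((s, s), spec.background_intensity, dtype=np.float64)
    img += (spec.bone_intensity - spec.background_intensity) * bone_field
    img[root] = spec.root_intensity
    img[crown] = spec.crown_intensity

    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, (s, s))
    if spec.streak_artifact_prob > 0 and rng.random() < spec.streak_artifact_prob:
        cx, cy = crown_centers[rng.integers(len(crown_centers))]
        theta = rng.uniform(0.0, np.pi)
        d = np.abs((xx - cx) * np.sin(theta) - (yy - cy) * np.cos(theta))
        img = img + 700.0 * np.exp(-0.5 * (d / 1.2) ** 2)
    img = np.clip(img, 0.0, 2500.0)

    band = 2
    structure = ndimage.generate_binary_structure(2, 1)
    dil = ndimage.binary_dilation(mask, structure, iterations=band)
    ero = ndimage.binary_erosion(mask, structure, iterations=band, border_value=0)
    boundary = dil & ~ero
    difficulty = (root.astype(np.uint8) * ROOT_FLAG) | (
        boundary.astype(np.uint8) * BOUNDARY_FLAG
    )
    return PhantomSample(
        image=img.astype(np.float32),
        mask=mask.astype(np.uint8),
        difficulty_map=difficulty,
        crown_mask=crown.astype(np.uint8),
        root_mask=root.astype(np.uint8),
    )


def generate_dataset(spec: PhantomSpec, n_volumes: int, slices_per_volume: int,
                     out_dir, spacing: float = 0.4) -> dict:
    """Write NIfTI image/label phantom volumes plus a JSON manifest.

    Volumes are stacks of independent slices (shape S x S x Z) at isotropic
    ``spacing`` mm, directly consumable by the preprocessing module.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for v in range(n_volumes):
        imgs, msks = [], []
        for k in range(slices_per_volume):
            sample = generate_slice(spec, v * slices_per_volume + k)
            imgs.append(sample.image)
            msks.append(sample.mask)
        img_vol = np.stack(imgs, axis=-1)
        msk_vol = np.stack(msks, axis=-1).astype(np.uint8)
        vid = f"phantom{v:03d}"
        img_path = out_dir / f"{vid}_image.nii.gz"
        lbl_path = out_dir / f"{vid}_label.nii.gz"
        sp = (spacing,) * 3
        save_volume(Volume(img_vol, sp), img_path)
        save_volume(Volume(msk_vol, sp), lbl_path)
        entries.append(
            {"id": vid, "image": img_path.name, "label": lbl_path.name,
             "n_slices": slices_per_volume}
        )
    manifest = {
        "spacing": spacing,
        "image_size": spec.image_size,
        "seed": spec.seed,
        "volumes": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
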