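"""Synthetic two-class brain-tumor slice phantoms.

Generates seeded 2D MRI-like slices with ground-truth tumor masks for
exercising the segmentation/feature/classification pipeline.  Class 1
emulates a low-grade-glioma-like lesion (smaller, rounder, milder internal
texture); class 2 emulates a high-grade/glioblastoma-like lesion (larger,
more irregular boundary, stronger texture).  Slices are 8-bit, optionally
wrapped in a bright skull annulus (T2-with-skull condition) and optionally
corrupted with additive Gaussian noise.

The phantom is deliberately schematic: a brain-shaped ellipse on a dark
background, a tumor built from an ellipse with a sinusoidal radial
perturbation, and low-pass-filtered noise as internal tumor texture.  It is
designed to give the watershed a detectable hyperintense lesion and the
texture features class-dependent statistics, not to be radiometrically
realistic MRI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomParams",
    "Slice",
    "PhantomDataset",
    "generate_slice",
    "generate_dataset",
    "add_gaussian_noise",
    "save_slice",
    "save_dataset",
]

# Background (air) and brain-parenchyma base intensities, 8-bit scale.
_AIR_LEVEL = 10.0
_BRAIN_LEVEL = 95.0
_TUMOR_LEVEL = 185.0
_SKULL_LEVEL = 230.0

# Per-class generator defaults: (tumor_area_range, boundary_irregularity,
# tumor_texture_contrast).  Class 2 is strictly larger on every axis.
_CLASS_DEFAULTS = {
    1: ((0.02, 0.05), 0.08, 16.0),
    2: ((0.05, 0.12), 0.18, 30.0),
}


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of a single synthetic tumor slice.

    ``tumor_area_range`` is the admissible tumor area as a fraction of the
    whole image area; every generated slice's true mask area lies inside it.
    ``boundary_irregularity`` is the relative amplitude of the sinusoidal
    radial perturbation of the tumor boundary (dimensionless, >= 0).
    ``tumor_texture_contrast`` is the standard deviation (intensity units)
    of the low-pass-filtered texture added inside the tumor.
    """

    class_id: int = 1
    image_size: int = 224
    tumor_area_range: tuple[float, float] | None = None
    boundary_irregularity: float | None = None
    tumor_texture_contrast: float | None = None
    skull: bool = False
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_id not in (1, 2):
            raise ValueError(f"class_id must be 1 or 2, got {self.class_id}")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        area, irreg, contrast = _CLASS_DEFAULTS[self.class_id]
        if self.tumor_area_range is None:
            object.__setattr__(self, "tumor_area_range", area)
        if self.boundary_irregularity is None:
            object.__setattr__(self, "boundary_irregularity", irreg)
        if self.tumor_texture_contrast is None:
            object.__setattr__(self, "tumor_texture_contrast", contrast)
        lo, hi = self.tumor_area_range
        if not (0.0 < lo < hi < 0.25):
            raise ValueError(
                f"tumor_area_range must satisfy 0 < lo < hi < 0.25, got {self.tumor_area_range}"
            )
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def modality(self) -> str:
        return "T2-like" if self.skull else "FLAIR-like"


@dataclass
class Slice:
    """A 2D intensity slice with its class label and ground truth.

    ``pixels`` is an 8-bit (H, W) grid; ``as_rgb()`` replicates it to the
    (H, W, 3) layout expected by image-net-style feature extractors.
    """

    pixels: np.ndarray
    label: int
    modality: str
    truth_mask: np.ndarray | None = None
    params: PhantomParams | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim == 3:  # accept replicated 3-channel input
            self.pixels = self.pixels[..., 0]
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
            if self.truth_mask.shape != self.pixels.shape:
                raise ValueError("truth_mask shape must match pixels")

    def as_rgb(self) -> np.ndarray:
        return np.repeat(self.pixels[:, :, None], 3, axis=2)


def _brain_axes(size: int) -> tuple[float, float]:
    # Half-axes of the brain ellipse: 0.85 / 0.70 of the image half-size.
    return 0.85 * size / 2.0, 0.70 * size / 2.0


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _tumor_mask(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Star-shaped tumor mask with its area fraction inside tumor_area_range."""
    size = params.image_size
    lo, hi = params.tumor_area_range
    width = hi - lo
    # Sample the target area in the interior of the range so that the finite
    # pixel-grid correction cannot push it outside.
    target = rng.uniform(lo + 0.15 * width, hi - 0.15 * width)
    amp = params.boundary_irregularity
    lobes = int(rng.integers(3, 7))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    # Base radius ignoring the perturbation; mean area of the perturbed star
    # is pi*r0^2*(1 + amp^2/2), corrected below by rescaling.
    r0 = np.sqrt(target * size * size / np.pi / (1.0 + amp * amp / 2.0))

    ax_b, ay_b = _brain_axes(size)
    r_max = r0 * (1.0 + amp) * 1.15
    margin = 4.0
    # Uniform center inside the shrunken brain ellipse (polar sqrt sampling).
    u, ang = rng.uniform(), rng.uniform(0.0, 2.0 * np.pi)
    rad = np.sqrt(u)
    cx = size / 2.0 + rad * np.cos(ang) * max(ax_b - r_max - margin, 1.0)
    cy = size / 2.0 + rad * np.sin(ang) * max(ay_b - r_max - margin, 1.0)

    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    profile = 1.0 + amp * np.sin(lobes * theta + phase)

    scale = 1.0
    mask = dist <= r0 * scale * profile
    for _ in range(4):  # area \propto scale^2 -> quasi-Newton rescale
        frac = mask.sum() / (size * size)
        if frac <= 0:
            scale *= 1.5
        else:
            scale *= np.sqrt(target / frac)
        mask = dist <= r0 * scale * profile
    frac = mask.sum() / (size * size)
    if not (lo < frac < hi):  # pragma: no cover - defensive
        raise RuntimeError(f"tumor area fraction {frac:.4f} escaped range {params.tumor_area_range}")
    return mask


def generate_slice(params: PhantomParams) -> Slice:
    """Generate one seeded phantom slice with its ground-truth tumor mask.

    Same ``params`` (including seed) give a bit-identical slice.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    ax_b, ay_b = _brain_axes(size)
    cx = cy = size / 2.0

    brain = _ellipse_mask(size, cx, cy, ax_b, ay_b)
    img = np.full((size, size), _AIR_LEVEL, dtype=float)

    # Brain parenchyma with mild smooth intensity variation.
    brain_tex = gaussian_filter(rng.standard_normal((size, size)), sigma=8.0)
    brain_tex *= 6.0 / max(brain_tex.std(), 1e-12)
    img[brain] = _BRAIN_LEVEL + brain_tex[brain]

    tumor = _tumor_mask(params, rng)
    tumor_tex = gaussian_filter(rng.standard_normal((size, size)), sigma=2.5)
    tumor_tex *= params.tumor_texture_contrast / max(tumor_tex.std(), 1e-12)
    img[tumor] = _TUMOR_LEVEL + tumor_tex[tumor]

    if params.skull:
        thickness = rng.uniform(4.0, 7.0)
        outer = _ellipse_mask(size, cx, cy, ax_b + thickness, ay_b + thickness)
        annulus = outer & ~brain
        img[annulus] = _SKULL_LEVEL + rng.uniform(-10.0, 10.0)

    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Slice(pixels=pixels, label=params.class_id, modality=params.modality,
                 truth_mask=tumor, params=params)


def add_gaussian_noise(slc: Slice, sigma: float, seed: int = 0) -> Slice:
    """Additive zero-mean Gaussian noise, clipped to [0, 255]; truth preserved."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return dataclasses.replace(slc, pixels=slc.pixels.copy())
    rng = np.random.default_rng(seed)
    noisy = slc.pixels.astype(float) + rng.normal(0.0, sigma, slc.pixels.shape)
    noisy = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return dataclasses.replace(slc, pixels=noisy)


@dataclass
class PhantomDataset:
    """Labeled phantom slices with a stratified train/val/test assignment."""

    slices: list[Slice]
    manifest: pd.DataFrame  # columns: index, label, split, seed
    seed: int
    split: tuple[float, float, float]

    def subset(self, split: str) -> list[Slice]:
        idx = self.manifest.index[self.manifest["split"] == split]
        return [self.slices[i] for i in idx]


def _split_counts(n: int, split: Sequence[float]) -> tuple[int, int, int]:
    # floor for val/test, remainder to train
    n_val = int(np.floor(n * split[1]))
    n_test = int(np.floor(n * split[2]))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(
    n_per_class: int,
    split: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    skull: bool = False,
    noise_sigma: float = 0.0,
    image_size: int = 224,
) -> PhantomDataset:
    """Generate a stratified two-class phantom dataset with disjoint splits."""
    split = tuple(float(f) for f in split)
    if len(split) != 3 or abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")

    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = _split_counts(n_per_class, split)
    slices: list[Slice] = []
    rows = []
    for class_id in (1, 2):
        labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        for i, part in enumerate(labels):
            child = int(rng.integers(0, 2**31 - 1))
            p = PhantomParams(class_id=class_id, image_size=image_size,
                              skull=skull, noise_sigma=noise_sigma, seed=child)
            slices.append(generate_slice(p))
            rows.append({"label": class_id, "split": part, "seed": child})
    manifest = pd.DataFrame(rows)
    return PhantomDataset(slices=slices, manifest=manifest, seed=seed, split=split)


def save_slice(slc: Slice, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a slice as 8-bit PNG (and optionally its mask as 0/255 PNG)."""
    Image.fromarray(slc.pixels).save(str(path))
    if mask_path is not None and slc.truth_mask is not None:
        Image.fromarray((slc.truth_mask * 255).astype(np.uint8)).save(str(mask_path))


def save_dataset(ds: PhantomDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write slices/masks as PNG plus a CSV manifest and YAML parameter sidecar."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for i, slc in enumerate(ds.slices):
        img_path = out / "images" / f"slice_{i:05d}.png"
        mask_path = out / "masks" / f"slice_{i:05d}.png"
        save_slice(slc, img_path, mask_path)
        row = ds.manifest.iloc[i]
        records.append({"path": str(img_path), "mask": str(mask_path),
                        "label": int(row["label"]), "split": row["split"],
                        "seed": int(row["seed"])})
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    sidecar = {"seed": ds.seed, "split": list(ds.split),
               "n_slices": len(ds.slices),
               "class_defaults": {str(k): {"tumor_area_range": list(v[0]),
                                           "boundary_irregularity": v[1],
                                           "tumor_texture_contrast": v[2]}
                                  for k, v in _CLASS_DEFAULTS.items()}}
    (out / "params.yaml").write_text(yaml.safe_dump(sidecar))
    return manifest
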