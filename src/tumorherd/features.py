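"""Handcrafted (GLCM texture, Hu shape) and deep feature extraction.

The texture block is 25 gray-level co-occurrence statistics computed on the
grayscale pixels of the tumor's bounding region: five statistics (contrast,
correlation, energy, homogeneity, entropy) at distance 1 for each of the
four directions 0/45/90/135 degrees, plus the same five statistics on the
direction-averaged matrix at distance 2.  The shape block is the first
three Hu invariant moments of the binary mask, reported on a signed-log10
scale.  Deep extractors embed a 224x224x3 slice into a 1x1000 vector; the
test path uses a deterministic seeded random-projection stub so that no
pretrained weights are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import moments_central, moments_hu, moments_normalized
from skimage.transform import resize

from .segmentation import TumorMask

__all__ = [
    "FeatureVector",
    "DeepExtractor",
    "StubExtractor",
    "glcm_features",
    "hu_features",
    "deep_features",
    "stub_extractor",
    "GLCM_STATS",
    "GLCM_ANGLES_DEG",
]

GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")
GLCM_ANGLES_DEG = (0, 45, 90, 135)
_GLCM_LEVELS = 8
DEEP_DIM = 1000


@dataclass
class FeatureVector:
    """Named, ordered 1D real feature vector with provenance."""

    values: np.ndarray
    names: list[str]
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def dim(self) -> int:
        return len(self.values)


@runtime_checkable
class DeepExtractor(Protocol):
    """Embeds a slice into a 1x1000 deep-feature vector, deterministically."""

    name: str

    def embed(self, slc) -> FeatureVector: ...


def _quantize(pixels: np.ndarray, levels: int = _GLCM_LEVELS) -> np.ndarray:
    return (pixels.astype(np.uint16) * levels // 256).astype(np.uint8)


def _glcm_stats(p: np.ndarray) -> list[float]:
    """The five statistics of one normalized symmetric co-occurrence matrix."""
    g = p[:, :, None, None]
    out = [float(graycoprops(g, prop)[0, 0])
           for prop in ("contrast", "correlation", "energy", "homogeneity")]
    nz = p[p > 0]
    out.append(float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0)
    return out


def glcm_features(pixels: np.ndarray, mask: TumorMask | np.ndarray) -> FeatureVector:
    """25 GLCM texture statistics of the tumor's bounding region.

    Matrices are computed at 8 gray levels, symmetric and normalized, on the
    grayscale crop of the mask's bounding box (the binary mask itself feeds
    the shape block only; binary co-occurrence would be degenerate).
    """
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        pixels = pixels[..., 0]
    if m.shape != pixels.shape:
        raise ValueError("mask/image shape mismatch")
    if not m.any():
        raise ValueError("empty mask")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    crop = pixels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    q = _quantize(crop)

    angles = [np.deg2rad(a) for a in GLCM_ANGLES_DEG]
    values: list[float] = []
    names: list[str] = []

    g1 = graycomatrix(q, distances=[1], angles=angles, levels=_GLCM_LEVELS,
                      symmetric=True, normed=True)
    per_angle = [_glcm_stats(g1[:, :, 0, k]) for k in range(len(angles))]
    for si, stat in enumerate(GLCM_STATS):
        for k, ang in enumerate(GLCM_ANGLES_DEG):
            values.append(per_angle[k][si])
            names.append(f"glcm_{stat}_d1_a{ang}")

    g2 = graycomatrix(q, distances=[2], angles=angles, levels=_GLCM_LEVELS,
                      symmetric=True, normed=True)
    avg = g2[:, :, 0, :].mean(axis=2)
    avg_stats = _glcm_stats(avg)
    for stat, val in zip(GLCM_STATS, avg_stats):
        values.append(val)
        names.append(f"glcm_{stat}_d2_avg")

    return FeatureVector(np.array(values), names, "GLCM")


def _signed_log10(h: np.ndarray) -> np.ndarray:
    out = np.zeros_like(h, dtype=float)
    nz = h != 0
    out[nz] = np.sign(h[nz]) * np.log10(np.abs(h[nz]))
    return out


def hu_features(mask: TumorMask | np.ndarray) -> FeatureVector:
    """First three Hu invariant moments of the binary mask, signed-log10 scale."""
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    mu = moments_central(m.astype(float))
    hu = moments_hu(moments_normalized(mu))
    return FeatureVector(_signed_log10(hu[:3]), [f"hu_{i + 1}" for i in range(3)], "Hu")


def deep_features(slc, extractor: DeepExtractor) -> FeatureVector:
    """Run a deep extractor on a slice; output contract is a 1x1000 vector."""
    fv = extractor.embed(slc)
    if fv.dim != DEEP_DIM:
        raise ValueError(f"extractor {extractor.name!r} returned dim {fv.dim}, expected {DEEP_DIM}")
    return fv


@dataclass
class StubExtractor:
    """Weight-free deterministic deep-feature stand-in.

    Embeds a slice by mean-pooling channels, downsampling to 32x32, and
    applying a fixed seeded Gaussian random projection to 1000 dimensions.
    The projection matrix depends only on the seed, so the embedding is
    reproducible across processes.
    """

    seed: int = 0
    name: str = field(init=False)

    def __post_init__(self) -> None:
        self.name = f"stub{self.seed}"
        rng = np.random.default_rng(self.seed)
        self._w = rng.standard_normal((DEEP_DIM, 32 * 32)) / np.sqrt(32 * 32)

    def _pooled(self, pixels: np.ndarray) -> np.ndarray:
        img = np.asarray(pixels, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        h, w = img.shape
        if h % 32 == 0 and w % 32 == 0:  # exact block-mean pooling
            small = img.reshape(32, h // 32, 32, w // 32).mean(axis=(1, 3))
        else:
            small = resize(img, (32, 32), anti_aliasing=True, preserve_range=True)
        return small.ravel() / 255.0

    def embed(self, slc) -> FeatureVector:
        pixels = slc.pixels if hasattr(slc, "pixels") else slc
        vec = self._w @ self._pooled(pixels)
        names = [f"{self.name}_{i}" for i in range(DEEP_DIM)]
        return FeatureVector(vec, names, self.name)


def stub_extractor(seed: int = 0) -> StubExtractor:
    return StubExtractor(seed=seed)
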