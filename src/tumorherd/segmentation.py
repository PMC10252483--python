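"""Tumor extraction: CLAHE enhancement + marker-controlled watershed.

The segmentation route is: contrast-limited adaptive histogram equalization,
Sobel gradient edge map, morphological open/close smoothing, internal
markers from the distance-transform cores of bright connected components
(components smaller than ``marker_size`` pixels are ignored),
marker-controlled watershed on the edge map, and selection of the brightest
compact non-background region.  FLAIR/T2 gliomas are hyperintense, so mean
enhanced intensity ranks candidate regions; a solidity floor rejects the
thin bright skull annulus present in T2-with-skull slices.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, measure, morphology, segmentation as skseg

__all__ = [
    "WatershedParams",
    "TumorMask",
    "clahe_enhance",
    "watershed_segment",
    "segment_slice",
    "postprocess_mask",
    "dice",
]

_MIN_SOLIDITY = 0.40  # skull annuli have solidity << this; blobs >> this


@dataclass(frozen=True)
class WatershedParams:
    clahe_clip: float = 1.0
    clahe_tiles: int = 2
    morph_radius: int = 2
    marker_size: int = 10
    min_tumor_area: int = 30

    def __post_init__(self) -> None:
        if self.marker_size < 1:
            raise ValueError("marker_size must be >= 1")
        if self.morph_radius < 1:
            raise ValueError("morph_radius must be >= 1")


@dataclass
class TumorMask:
    """Binary tumor segmentation with provenance."""

    mask: np.ndarray
    marker_count: int
    provenance: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return self.area == 0


def clahe_enhance(pixels: np.ndarray, clip: float = 1.0, tiles: int = 2) -> np.ndarray:
    """CLAHE on an 8-bit grid; returns an 8-bit grid in [0, 255].

    ``clip`` follows the common OpenCV-style scale; it maps to the
    scikit-image clip-limit fraction as clip/100.
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0 or pixels.ndim != 2:
        raise ValueError("expected a non-empty 2D intensity grid")
    if pixels.max() == pixels.min():
        return pixels.astype(np.uint8).copy()
    kernel = (max(pixels.shape[0] // tiles, 1), max(pixels.shape[1] // tiles, 1))
    out = exposure.equalize_adapthist(pixels.astype(np.uint8), kernel_size=kernel,
                                      clip_limit=clip / 100.0)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def _empty_result(shape: tuple[int, int], params: WatershedParams) -> TumorMask:
    return TumorMask(np.zeros(shape, dtype=bool), 0, asdict(params))


def postprocess_mask(mask: np.ndarray, min_area: int = 30) -> np.ndarray:
    """Hole-fill, keep largest component, clear border; idempotent."""
    mask = ndi.binary_fill_holes(np.asarray(mask, dtype=bool))
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    elif n == 0:
        return np.zeros_like(mask)
    mask = skseg.clear_border(mask)
    if mask.sum() < min_area:
        return np.zeros_like(mask)
    return mask


def watershed_segment(pixels: np.ndarray, params: WatershedParams | None = None) -> TumorMask:
    """Extract the tumor region from an enhanced slice.

    Returns an empty mask when no candidate region survives (blank input,
    no sufficiently large markers, or all regions below ``min_tumor_area``).
    """
    params = params or WatershedParams()
    img = np.asarray(pixels)
    if img.ndim == 3:
        img = img[..., 0]
    if min(img.shape) < 32:
        raise ValueError("image smaller than 32x32")
    img = img.astype(np.uint8)
    if img.max() == img.min():
        return _empty_result(img.shape, params)

    fimg = img.astype(float)
    selem = morphology.disk(params.morph_radius)
    smooth = morphology.closing(morphology.opening(img, selem), selem)
    # Gradient of the morphologically flattened, lightly blurred image:
    # lesion-boundary edges must dominate internal-texture and noise edges,
    # otherwise basins leak through the boundary before filling the lesion.
    edge = filters.sobel(ndi.gaussian_filter(smooth.astype(float), 1.5) / 255.0)

    # Bright-structure foreground: top class of a 3-class Otsu split
    # (air | brain | bright lesion-or-skull).
    try:
        thr_low, thr = filters.threshold_multiotsu(smooth, classes=3)
    except ValueError:  # too few distinct levels
        return _empty_result(img.shape, params)
    fg = smooth > thr
    # Bright structures touching air (skull annulus, boundary rim artifacts)
    # cannot be tumor: gliomas sit inside parenchyma.  Drop them before the
    # fragment-merging closing so they never seed a marker.
    air_adjacent = morphology.dilation(smooth <= thr_low, morphology.disk(2))
    pre_labels, n_pre = ndi.label(fg)
    for comp in range(1, n_pre + 1):
        sel = pre_labels == comp
        if (sel & air_adjacent).sum() > 0.05 * sel.sum():
            fg[sel] = False
    # Merge texture-split fragments of one lesion into a single component so
    # each lesion seeds exactly one internal marker.
    fg = morphology.closing(fg, morphology.disk(3 * params.morph_radius))
    # Fill holes per component, but leave ring-shaped components (a skull
    # annulus) unfilled: filling a ring would swallow the whole brain.
    comp_labels, n_comp = ndi.label(fg)
    filled = np.zeros_like(fg)
    for comp in range(1, n_comp + 1):
        sel = comp_labels == comp
        sel_filled = ndi.binary_fill_holes(sel)
        filled |= sel_filled if sel_filled.sum() <= 2.5 * sel.sum() else sel
    fg = morphology.remove_small_objects(filled, max_size=params.marker_size - 1)
    if not fg.any():
        return _empty_result(img.shape, params)

    dist = ndi.distance_transform_edt(fg)
    comp_labels, n_comp = ndi.label(fg)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[0, :] = markers[-1, :] = 1  # background marker: image frame
    markers[:, 0] = markers[:, -1] = 1
    marker_id = 2
    for comp in range(1, n_comp + 1):
        sel = comp_labels == comp
        if sel.sum() < params.marker_size:
            continue
        # Marker = the high-distance core of the component (everything at
        # 40% or more of the component's peak depth).  A single-pixel seed
        # is too easy to conquer when internal texture out-ridges a weak
        # spot of the lesion boundary; an area marker claims the interior.
        d = np.where(sel, dist, -1.0)
        markers[d >= max(2.0, 0.4 * d.max())] = marker_id
        marker_id += 1
    n_markers = marker_id - 2
    if n_markers == 0:
        return _empty_result(img.shape, params)

    # External (tissue) markers: mid-intensity parenchyma, eroded away from
    # boundaries.  Without them the lesion basin would flood the whole brain.
    tissue = (smooth > thr_low) & ~fg
    tissue = morphology.erosion(tissue, morphology.disk(3 * params.morph_radius))
    tissue_labels, n_tissue = ndi.label(tissue)
    for comp in range(1, n_tissue + 1):
        sel = tissue_labels == comp
        if sel.sum() < params.marker_size:
            continue
        idx = np.transpose(np.nonzero(sel))
        r, c = idx[len(idx) // 2]
        if markers[r, c] == 0:
            markers[r, c] = marker_id
            marker_id += 1

    ws = skseg.watershed(edge, markers)

    air_basin = morphology.dilation(ws == 1, morphology.disk(2))
    best_label, best_score = 0, -np.inf
    for region in measure.regionprops(ws, intensity_image=fimg):
        if region.label == 1:  # background basin
            continue
        if region.area < params.min_tumor_area:
            continue
        if region.area > 0.25 * img.size:
            continue  # larger than any plausible tumor: a flooded brain basin
        if region.solidity < _MIN_SOLIDITY:
            continue  # thin ring (skull) or straggly region
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if air_basin[rr, cc].sum() > 0.05 * region.area:
            continue  # abuts the air basin: skull remnant or boundary rim
        if region.intensity_mean > best_score:
            best_score = region.intensity_mean
            best_label = region.label
    if best_label == 0:
        return _empty_result(img.shape, params)

    mask = postprocess_mask(ws == best_label, min_area=params.min_tumor_area)
    return TumorMask(mask, n_markers, asdict(params))


def segment_slice(pixels: np.ndarray, params: WatershedParams | None = None) -> TumorMask:
    """Full extraction route: CLAHE enhancement, then marker watershed."""
    params = params or WatershedParams()
    enhanced = clahe_enhance(pixels, clip=params.clahe_clip, tiles=params.clahe_tiles)
    return watershed_segment(enhanced, params)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A.B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / total
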