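"""Background/tissue separation for brightfield sections.

The recipe: downscale the scan to a working resolution, tile it with a
quadtree driven by a brightness-homogeneity criterion, estimate background
brightness from the largest (most homogeneous) squares and tissue brightness
from the median over all squares, threshold at the midpoint, absorb small
tissue specks enclosed by background, smooth the tissue/background border
with surface-tension-constrained (boundary-restricted, perimeter-non-
increasing) majority relaxation, and finally synchronize the working-
resolution mask back to the full-resolution image on which object detection
runs.

Brightness is the unweighted mean of the R, G and B channels throughout
(configurable luma weights are accepted where noted).  Brightfield images
have their brightest pixels in the background, so the tissue estimate must
fall below the background estimate; inverted-contrast input is flagged as
degenerate rather than guessed at.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.morphology import disk


@dataclasses.dataclass(frozen=True)
class QuadtreeBlock:
    """One square of the quadtree tiling, clipped to the image extent.

    ``side`` is the nominal (power-of-two) side on the padded canvas;
    ``height``/``width`` give the clipped extent actually covered.
    """

    row: int
    col: int
    side: int
    height: int
    width: int
    mean: float
    sd: float

    @property
    def area(self) -> int:
        return self.height * self.width


@dataclasses.dataclass
class QuadtreeSegmentation:
    blocks: list[QuadtreeBlock]
    homogeneity_sd: float
    min_side: int
    shape: tuple[int, int]

    def tiled_area(self) -> int:
        return sum(b.area for b in self.blocks)


@dataclasses.dataclass
class BrightnessLevels:
    background: float
    tissue: float
    degenerate: bool

    @property
    def threshold(self) -> float:
        return 0.5 * (self.background + self.tissue)


@dataclasses.dataclass
class TissueMask:
    """Binary tissue partition at working and full resolution."""

    working: np.ndarray
    full: np.ndarray
    background_brightness: float
    tissue_brightness: float
    threshold: float


def brightness(image: np.ndarray, weights: tuple[float, float, float] | None = None) -> np.ndarray:
    """Per-pixel brightness of an RGB image as float64.

    Default is the unweighted channel mean; pass e.g. Rec.601 luma weights
    (0.299, 0.587, 0.114) to change the definition.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    if weights is None:
        return img.mean(axis=2)
    w = np.asarray(weights, dtype=np.float64)
    return img @ (w / w.sum())


def downscale(image: np.ndarray, factor: float = 0.125) -> np.ndarray:
    """Area-average (block-mean) downscaling.

    Output dimensions are ``ceil(input * factor)``; each output pixel is the
    mean of the input pixels in its block of the induced partition (blocks
    are equal-sized whenever the factor divides the image evenly, as with
    the default 1/8 on scanner-typical sizes).
    """
    if not 0 < factor <= 1:
        raise ValueError(f"downscale factor must be in (0, 1], got {factor}")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    out_h = int(np.ceil(h * factor))
    out_w = int(np.ceil(w * factor))
    rb = (np.arange(out_h) * h) // out_h
    cb = (np.arange(out_w) * w) // out_w
    flat = img.reshape(h, w, -1)
    sums = np.add.reduceat(np.add.reduceat(flat, rb, axis=0), cb, axis=1)
    rlen = np.diff(np.append(rb, h)).astype(np.float64)
    clen = np.diff(np.append(cb, w)).astype(np.float64)
    counts = rlen[:, None] * clen[None, :]
    out = sums / counts[:, :, None]
    return out.reshape(out.shape[:2] + image.shape[2:]) if image.ndim == 3 else out[:, :, 0]


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def quadtree_segment(
    image: np.ndarray,
    homogeneity_sd: float = 5.0,
    min_side: int = 4,
    brightness_weights: tuple[float, float, float] | None = None,
) -> QuadtreeSegmentation:
    """Recursively quarter the image into squares until each is homogeneous.

    The canvas is padded to the next power of two; padding never enters a
    block (fully padded squares are dropped, partially padded squares are
    clipped).  A square splits iff the population SD of its brightness
    exceeds ``homogeneity_sd`` and its nominal side exceeds ``min_side``.
    The kept blocks tile the image exactly.
    """
    b = brightness(image, brightness_weights)
    h, w = b.shape
    if h == 0 or w == 0:
        raise ValueError("cannot segment an empty image")
    root = _next_pow2(max(h, w))
    blocks: list[QuadtreeBlock] = []
    stack = [(0, 0, root)]
    while stack:
        r0, c0, side = stack.pop()
        if r0 >= h or c0 >= w:
            continue  # fully in the padding
        r1, c1 = min(r0 + side, h), min(c0 + side, w)
        sub = b[r0:r1, c0:c1]
        sd = float(sub.std())
        if sd > homogeneity_sd and side > min_side and side > 1:
            half = side // 2
            stack.extend(
                [(r0, c0, half), (r0, c0 + half, half), (r0 + half, c0, half), (r0 + half, c0 + half, half)]
            )
        else:
            blocks.append(
                QuadtreeBlock(
                    row=r0, col=c0, side=side, height=r1 - r0, width=c1 - c0,
                    mean=float(sub.mean()), sd=sd,
                )
            )
    return QuadtreeSegmentation(blocks=blocks, homogeneity_sd=homogeneity_sd, min_side=min_side, shape=(h, w))


def estimate_brightness_levels(segmentation: QuadtreeSegmentation) -> BrightnessLevels:
    """Estimate background and tissue brightness from the quadtree tiling.

    Background: median brightness of the largest squares (the image is most
    homogeneous over the empty background, so those squares grow largest).
    Tissue: median brightness over all squares — the vast majority of
    squares lie on tissue.  If the two estimates do not satisfy
    background > tissue the result is flagged degenerate and the caller must
    supply a threshold manually.
    """
    if not segmentation.blocks:
        raise ValueError("empty quadtree segmentation")
    max_side = max(b.side for b in segmentation.blocks)
    largest = [b.mean for b in segmentation.blocks if b.side == max_side]
    background = float(np.median(largest))
    tissue = float(np.median([b.mean for b in segmentation.blocks]))
    return BrightnessLevels(background=background, tissue=tissue, degenerate=background <= tissue)


def threshold_tissue(
    image: np.ndarray,
    background: float,
    tissue: float,
    brightness_weights: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Classify pixels as tissue where brightness falls below the midpoint
    of the background and tissue estimates."""
    if not background > tissue:
        raise ValueError(
            f"degenerate brightness estimates (background {background} <= tissue {tissue}); "
            "supply a manual threshold"
        )
    mid = 0.5 * (background + tissue)
    return brightness(image, brightness_weights) < mid


def absorb_enclosed_regions(mask: np.ndarray, max_fraction: float = 0.001) -> np.ndarray:
    """Relabel as background small tissue components fully enclosed by it.

    A 4-connected tissue component is enclosed iff it does not touch the
    image border; it is absorbed when its area is <= max_fraction of the
    image area (the limit is inclusive).
    """
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return mask.copy()
    limit = max_fraction * mask.size
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touches = np.zeros(n + 1, bool)
    touches[np.unique(labels[border])] = True
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    absorb = (~touches) & (areas <= limit)
    absorb[0] = False
    return mask & ~absorb[labels]


def _boundary_length(mask: np.ndarray) -> int:
    """Number of 4-adjacent pixel pairs with discordant labels."""
    m = np.asarray(mask, bool)
    return int(np.sum(m[1:, :] != m[:-1, :]) + np.sum(m[:, 1:] != m[:, :-1]))


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, bool)
    pad_t = np.pad(m, 1, mode="edge")
    diff = (
        (pad_t[:-2, 1:-1] != m)
        | (pad_t[2:, 1:-1] != m)
        | (pad_t[1:-1, :-2] != m)
        | (pad_t[1:-1, 2:] != m)
    )
    return diff


def surface_tension_grow(mask: np.ndarray, iterations: int = 3, radius: int = 2) -> np.ndarray:
    """Smooth the tissue/background border by boundary-restricted majority
    relaxation.

    Each iteration, every pixel on the boundary (having a 4-neighbour of the
    opposite label) adopts the majority label within a disc of the given
    radius; ties keep the current label and interior pixels never change.
    The total boundary length is non-increasing by construction: an
    iteration whose result would lengthen the boundary is discarded and the
    relaxation stops.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    current = np.asarray(mask, bool).copy()
    if iterations == 0:
        return current
    kernel = disk(radius).astype(np.float64)
    ones = np.ones_like(current, dtype=np.float64)
    valid = ndimage.convolve(ones, kernel, mode="constant", cval=0.0)
    length = _boundary_length(current)
    for _ in range(iterations):
        boundary = _boundary_pixels(current)
        if not boundary.any():
            break
        tissue_votes = ndimage.convolve(current.astype(np.float64), kernel, mode="constant", cval=0.0)
        majority_tissue = tissue_votes * 2 > valid
        majority_bg = tissue_votes * 2 < valid
        proposal = current.copy()
        proposal[boundary & majority_tissue] = True
        proposal[boundary & majority_bg] = False
        new_length = _boundary_length(proposal)
        if new_length > length:
            break
        if np.array_equal(proposal, current):
            break  # fixed point
        current = proposal
        length = new_length
    return current


def synchronize_full_resolution(working_mask: np.ndarray, full_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upscale of the working mask to the full resolution.

    Uses the same block partition as :func:`downscale`, so every
    full-resolution pixel maps to exactly the working pixel whose block it
    belongs to.
    """
    m = np.asarray(working_mask, bool)
    h, w = m.shape
    H, W = full_shape
    if H < h or W < w:
        raise ValueError(f"full shape {full_shape} smaller than working shape {(h, w)}")
    if abs(H / h - W / w) > 0.51 and min(h, w) > 1:
        raise ValueError(f"incompatible shapes: working {(h, w)} vs full {full_shape}")
    rb = (np.arange(h) * H) // h
    cb = (np.arange(w) * W) // w
    rmap = np.searchsorted(rb, np.arange(H), side="right") - 1
    cmap = np.searchsorted(cb, np.arange(W), side="right") - 1
    return m[np.ix_(rmap, cmap)]


def white_exclusion_mask(image: np.ndarray, tissue_full: np.ndarray, cutoff: float = 250.0) -> np.ndarray:
    """Near-white pixels inside tissue, to be excluded from measurement areas.

    Tendon areas that appear white in the processed scan carry no stain
    information; pixels at or above the brightness cutoff are dropped from
    the other-tissue area accounting.
    """
    return (brightness(image) >= cutoff) & np.asarray(tissue_full, bool)


def segment_tissue(
    image: np.ndarray,
    downscale_factor: float = 0.125,
    homogeneity_sd: float = 5.0,
    min_block_side: int = 4,
    enclosed_max_fraction: float = 0.001,
    grow_iterations: int = 3,
    grow_radius: int = 2,
    manual_mask: np.ndarray | None = None,
    brightness_weights: tuple[float, float, float] | None = None,
) -> TissueMask:
    """Full background/tissue separation pipeline on one slide.

    ``manual_mask`` (working resolution) optionally restricts the analysis
    to a hand-delineated scanning region, standing in for manual tendon
    delineation.
    """
    working = downscale(image, downscale_factor)
    seg = quadtree_segment(working, homogeneity_sd, min_block_side, brightness_weights)
    levels = estimate_brightness_levels(seg)
    if levels.degenerate:
        raise ValueError(
            "degenerate brightness estimates: image appears to lack a bright background"
        )
    provisional = threshold_tissue(working, levels.background, levels.tissue, brightness_weights)
    if manual_mask is not None:
        provisional &= np.asarray(manual_mask, bool)
    cleaned = absorb_enclosed_regions(provisional, enclosed_max_fraction)
    smoothed = surface_tension_grow(cleaned, grow_iterations, grow_radius)
    full = synchronize_full_resolution(smoothed, image.shape[:2])
    return TissueMask(
        working=smoothed,
        full=full,
        background_brightness=levels.background,
        tissue_brightness=levels.tissue,
        threshold=levels.threshold,
    )
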