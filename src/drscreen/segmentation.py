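"""Fundus preprocessing and segmentation.

The chain isolates high-frequency retinal structure — blood vessels, hard
exudates and microaneurysms — from a colour fundus photograph:

    resize (512x512) -> grayscale -> histogram equalization
    -> 9x9 mean subtraction -> Ridler-Calvard global threshold -> binarize
    -> small-cluster removal -> complement -> overlay on the gray image

Images are carried as NumPy arrays: RGB as ``(H, W, 3)``, grayscale as
``(H, W)`` floats in ``[0, 1]`` (8-bit integer inputs are converted on
entry), binary masks as ``{0, 1}`` uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects
from skimage.transform import resize as _skimage_resize

__all__ = [
    "SegmentationResult",
    "as_float",
    "resize_image",
    "to_grayscale",
    "equalize_histogram",
    "local_average",
    "subtract_background",
    "ridler_calvard_threshold",
    "binarize",
    "remove_small_components",
    "complement",
    "overlay",
    "segment_fundus",
]

# ITU-R BT.601 luma weights
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class SegmentationResult:
    """Output bundle of :func:`segment_fundus`.

    Attributes
    ----------
    gray : ndarray
        Resized grayscale image in [0, 1].
    mask : ndarray
        Binary foreground mask (vessels/exudates/MAs = 1) after
        small-cluster removal.
    segmented : ndarray
        Grayscale image restricted to the mask support (zero elsewhere).
    threshold : float
        Converged Ridler-Calvard threshold on the normalized subtracted
        image, in [0, 1].
    degenerate : bool
        True when the subtracted image carried no high-frequency content
        (constant input); the mask is then empty by definition.
    stages : dict
        Every intermediate image keyed by stage name, for inspection and
        for the CLI's ``--save-stages``.
    """

    gray: np.ndarray
    mask: np.ndarray
    segmented: np.ndarray
    threshold: float
    degenerate: bool = False
    stages: dict = field(default_factory=dict)


def as_float(img: np.ndarray) -> np.ndarray:
    """Return the image as float64 in [0, 1] (integer inputs divided by 255)."""
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def resize_image(img: np.ndarray, side: int = 512) -> np.ndarray:
    """Resize to a fixed ``side`` x ``side`` raster with bilinear interpolation.

    Aspect ratio is deliberately not preserved: every image is forced to the
    same square working size so all downstream operators see one geometry.
    A same-size input is returned pixel-identical.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    spatial = img.shape[:2]
    if spatial == (side, side):
        return img.copy()
    out_shape = (side, side) + img.shape[2:]
    return _skimage_resize(
        img, out_shape, order=1, mode="reflect", anti_aliasing=False, preserve_range=True
    )


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to a single luminance channel (BT.601 weights)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return as_float(img) @ _LUMA_WEIGHTS


def equalize_histogram(gray: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Histogram equalization: map each level through the image CDF.

    Levels are the ``nbins`` equal-width bins of [0, 1]; an occupied level k
    maps to CDF(k), so output values lie in (0, 1] and the level mapping is
    monotone non-decreasing.  A constant image maps to all ones.
    """
    g = as_float(gray)
    if g.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {g.shape}")
    levels = np.clip((g * nbins).astype(np.int64), 0, nbins - 1)
    counts = np.bincount(levels.ravel(), minlength=nbins)
    cdf = np.cumsum(counts) / levels.size
    return cdf[levels]


def local_average(gray: np.ndarray, size: int = 9) -> np.ndarray:
    """Mean filter with an all-ones ``size`` x ``size`` mask (sum / size^2).

    Border handling is replicate padding, so a constant image is a fixed
    point of the filter.
    """
    if size < 3 or size % 2 == 0:
        raise ValueError(f"filter size must be an odd integer >= 3, got {size}")
    g = as_float(gray)
    if g.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {g.shape}")
    return ndimage.uniform_filter(g, size=size, mode="nearest")


def subtract_background(equalized: np.ndarray, averaged: np.ndarray) -> np.ndarray:
    """Pixelwise ``equalized - averaged`` with negatives clipped to zero.

    Removing the local mean discards slowly varying background and keeps
    only high-frequency structure; clipping keeps intensities nonnegative
    for the thresholding stage.
    """
    equalized = as_float(equalized)
    averaged = as_float(averaged)
    if equalized.shape != averaged.shape:
        raise ValueError(
            f"shape mismatch: {equalized.shape} vs {averaged.shape}"
        )
    return np.clip(equalized - averaged, 0.0, None)


def ridler_calvard_threshold(
    gray: np.ndarray, tol: float = 1e-4, max_iter: int = 100
) -> float:
    """Iterative intermeans (Ridler-Calvard) global threshold.

    Starting from T = 0.5 (half the dynamic range of a [0, 1] image), the
    threshold is replaced by the average of the foreground mean
    (pixels >= T) and background mean (pixels < T) until it moves by less
    than ``tol``.  For a constant image the split is undefined; the constant
    value itself is returned as the degenerate result.
    """
    g = as_float(gray).ravel()
    if g.size == 0:
        raise ValueError("cannot threshold an empty image")
    if g.min() < 0 or g.max() > 1:
        raise ValueError("input must be normalized to [0, 1]")
    lo, hi = g.min(), g.max()
    if hi - lo == 0:
        return float(lo)
    t = 0.5
    # If the start splits nothing off (all pixels on one side), restart from
    # the mid-range so both sides are nonempty for non-constant input.
    if t <= lo or t > hi:
        t = (lo + hi) / 2.0
    for _ in range(max_iter):
        fg = g[g >= t]
        bg = g[g < t]
        if fg.size == 0 or bg.size == 0:
            t = (lo + hi) / 2.0
            continue
        t_new = (fg.mean() + bg.mean()) / 2.0
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def binarize(gray: np.ndarray, t: float) -> np.ndarray:
    """Threshold to a {0, 1} mask; pixels >= t (inclusive) become white."""
    g = as_float(gray)
    return (g >= t).astype(np.uint8)


def remove_small_components(mask: np.ndarray, max_discard: int = 50) -> np.ndarray:
    """Discard 8-connected white clusters with ``max_discard`` or fewer pixels."""
    m = np.asarray(mask).astype(bool)
    cleaned = remove_small_objects(m, max_size=max_discard, connectivity=2)
    return cleaned.astype(np.uint8)


def complement(mask: np.ndarray) -> np.ndarray:
    """Logical complement of a binary mask (involution)."""
    m = np.asarray(mask)
    return (1 - m).astype(np.uint8)


def overlay(mask: np.ndarray, gray: np.ndarray) -> np.ndarray:
    """Keep grayscale values on the mask support, zero elsewhere."""
    mask = np.asarray(mask)
    gray = as_float(gray)
    if mask.shape != gray.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {gray.shape}")
    return gray * mask


def segment_fundus(
    img: np.ndarray,
    side: int = 512,
    mask_size: int = 9,
    max_discard: int = 50,
) -> SegmentationResult:
    """Run the full segmentation chain on an RGB fundus image.

    The subtracted image is re-normalized to [0, 1] before thresholding.
    An input with no high-frequency content (constant subtracted image)
    yields an empty mask and an all-zero segmented image, flagged
    degenerate.
    """
    resized = resize_image(img, side=side)
    gray = to_grayscale(resized)
    eq = equalize_histogram(gray)
    avg = local_average(eq, size=mask_size)
    sub = subtract_background(eq, avg)

    stages = {
        "resized": resized,
        "gray": gray,
        "equalized": eq,
        "averaged": avg,
        "subtracted": sub,
    }

    rng = sub.max() - sub.min()
    if rng <= 0:
        mask = np.zeros_like(sub, dtype=np.uint8)
        comp = complement(mask)
        segmented = overlay(mask, gray)
        stages.update(
            {"thresholded": mask, "cleaned": mask, "complemented": comp, "segmented": segmented}
        )
        return SegmentationResult(
            gray=gray, mask=mask, segmented=segmented, threshold=0.0,
            degenerate=True, stages=stages,
        )

    norm = (sub - sub.min()) / rng
    t = ridler_calvard_threshold(norm)
    binary = binarize(norm, t)
    cleaned = remove_small_components(binary, max_discard=max_discard)
    comp = complement(cleaned)
    segmented = overlay(cleaned, gray)
    stages.update(
        {"thresholded": binary, "cleaned": cleaned, "complemented": comp, "segmented": segmented}
    )
    return SegmentationResult(
        gray=gray, mask=cleaned, segmented=segmented, threshold=t,
        degenerate=False, stages=stages,
    )
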