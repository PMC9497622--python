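"""Gray-level co-occurrence matrices and the ten texture statistics.

A GLCM ``G(i, j)`` counts how often a pixel of quantized level *i* has a
neighbour of level *j* at a fixed displacement.  Normalizing by the total
count gives a joint distribution ``P`` over level pairs, from which the
texture statistics are computed:

* contrast        sum P(i,j) (i-j)^2
* energy          sum P(i,j)^2
* entropy         -sum P(i,j) ln P(i,j)
* homogeneity     sum P(i,j) / (1 + (i-j)^2)
* correlation     sum P(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)
* rms             sqrt( sum P(i,j)^2 / (N-1) )
* skewness        sum (P(i,j)-mu)^3 / ((N-1) sigma^3)
* kurtosis        sum (P(i,j)-mu)^4 / ((N-1) sigma^4)
* glcm_mean       mu_i   (marginal mean over row levels)
* glcm_variance   sigma_i^2

where mu_i, sigma_i are the row-marginal mean/SD of the level distribution
and mu, sigma are the mean/SD of the N^2 matrix entries themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from drscreen.exceptions import UndefinedStatisticError
from drscreen.segmentation import as_float

__all__ = [
    "FEATURE_NAMES",
    "CoocMatrix",
    "CoocStats",
    "FeatureVector",
    "quantize_levels",
    "compute_glcm",
    "normalize_glcm",
    "cooc_stats",
    "contrast",
    "energy",
    "entropy",
    "homogeneity",
    "correlation",
    "entry_moments",
    "extract_feature_vector",
    "extract_feature_table",
]

FEATURE_NAMES = (
    "contrast",
    "energy",
    "entropy",
    "homogeneity",
    "correlation",
    "rms",
    "skewness",
    "kurtosis",
    "glcm_mean",
    "glcm_variance",
)


@dataclass
class CoocMatrix:
    """Raw pair counts for one displacement.

    ``degenerate`` is set when the image admitted no in-bounds pixel pair
    under the offset (e.g. a 1x1 image), in which case ``counts`` is all
    zero.
    """

    counts: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool = False
    degenerate: bool = False


@dataclass
class CoocStats:
    """Moments of a normalized GLCM used by correlation and entry moments."""

    mu_i: float
    mu_j: float
    sigma_i: float
    sigma_j: float
    entry_mean: float
    entry_sd: float


@dataclass
class FeatureVector:
    contrast: float
    energy: float
    entropy: float
    homogeneity: float
    correlation: float
    rms: float
    skewness: float
    kurtosis: float
    glcm_mean: float
    glcm_variance: float
    degenerate: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def quantize_levels(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform equal-width binning of a [0, 1] image into integer levels.

    The maximum representable input (1.0) maps to ``levels - 1``.  8-bit
    integer inputs are first rescaled to [0, 1], so ``levels=256`` is the
    identity mapping on them.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    g = as_float(gray)
    return np.clip((g * levels).astype(np.int64), 0, levels - 1)


def compute_glcm(
    indexed: np.ndarray,
    levels: int | None = None,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
) -> CoocMatrix:
    """Count co-occurring level pairs at one pixel displacement.

    ``G(a, b)`` is the number of positions ``p`` with ``indexed[p] == a``
    and ``indexed[p + offset] == b``, counting only in-bounds pairs.  With
    ``symmetric=True`` the transpose is added, making the matrix direction-
    insensitive.
    """
    a = np.asarray(indexed)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D indexed image, got shape {a.shape}")
    if levels is None:
        levels = int(a.max()) + 1 if a.size else 1
    if a.size and (a.min() < 0 or a.max() >= levels):
        raise ValueError("indexed values must lie in [0, levels)")
    dr, dc = offset
    h, w = a.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return CoocMatrix(
            counts=np.zeros((levels, levels), dtype=np.int64),
            levels=levels, offset=(dr, dc), symmetric=symmetric, degenerate=True,
        )
    src = a[r0:r1, c0:c1].ravel()
    dst = a[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(src * levels + dst, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(np.int64)
    if symmetric:
        counts = counts + counts.T
    return CoocMatrix(counts=counts, levels=levels, offset=(dr, dc), symmetric=symmetric)


def normalize_glcm(glcm: CoocMatrix | np.ndarray) -> np.ndarray:
    """Divide each element by the total count, giving probabilities summing to 1."""
    counts = glcm.counts if isinstance(glcm, CoocMatrix) else np.asarray(glcm)
    total = counts.sum()
    if total == 0:
        raise UndefinedStatisticError("cannot normalize an all-zero co-occurrence matrix")
    return counts / total


def cooc_stats(p: np.ndarray) -> CoocStats:
    """Marginal and entry moments of a normalized GLCM.

    The marginal SDs are the square roots of the level-weighted second
    central moments; entry mean/SD are taken over all N^2 matrix entries
    (population SD).
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    i = np.arange(n).reshape(-1, 1)
    j = np.arange(n).reshape(1, -1)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    sigma_i = float(np.sqrt((p * (i - mu_i) ** 2).sum()))
    sigma_j = float(np.sqrt((p * (j - mu_j) ** 2).sum()))
    entry_mean = float(p.mean())
    entry_sd = float(p.std())
    return CoocStats(mu_i, mu_j, sigma_i, sigma_j, entry_mean, entry_sd)


def contrast(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    i = np.arange(n).reshape(-1, 1)
    j = np.arange(n).reshape(1, -1)
    return float((p * (i - j) ** 2).sum())


def energy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    return float((p ** 2).sum())


def entropy(p: np.ndarray) -> float:
    """Shannon entropy of the pair distribution, natural log, 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def homogeneity(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    i = np.arange(n).reshape(-1, 1)
    j = np.arange(n).reshape(1, -1)
    return float((p / (1.0 + (i - j) ** 2)).sum())


def correlation(p: np.ndarray, stats: CoocStats | None = None) -> float:
    """Level-pair correlation; undefined when either marginal SD is zero."""
    p = np.asarray(p, dtype=float)
    if stats is None:
        stats = cooc_stats(p)
    if stats.sigma_i == 0 or stats.sigma_j == 0:
        raise UndefinedStatisticError("correlation undefined: zero marginal variance")
    n = p.shape[0]
    i = np.arange(n).reshape(-1, 1)
    j = np.arange(n).reshape(1, -1)
    num = (p * (i - stats.mu_i) * (j - stats.mu_j)).sum()
    return float(num / (stats.sigma_i * stats.sigma_j))


def entry_moments(p: np.ndarray, stats: CoocStats | None = None) -> tuple[float, float, float]:
    """(rms, skewness, kurtosis) over the N^2 normalized entries.

    rms = sqrt(sum P^2 / (N-1)); skewness and kurtosis are the third and
    fourth moments of the entries about their mean, scaled by
    1/((N-1) sigma^k).  With zero entry SD (e.g. a uniform matrix) the
    standardized moments are undefined.
    """
    p = np.asarray(p, dtype=float)
    if stats is None:
        stats = cooc_stats(p)
    n = p.shape[0]
    rms = float(np.sqrt((p ** 2).sum() / (n - 1)))
    if stats.entry_sd == 0:
        raise UndefinedStatisticError("skewness/kurtosis undefined: zero entry variance")
    centred = p - stats.entry_mean
    skew = float((centred ** 3).sum() / ((n - 1) * stats.entry_sd ** 3))
    kurt = float((centred ** 4).sum() / ((n - 1) * stats.entry_sd ** 4))
    return rms, skew, kurt


def extract_feature_vector(
    segmented: np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
) -> FeatureVector:
    """Compute the ten texture statistics of a segmented grayscale image.

    Background zeros are included in the GLCM: the statistics describe the
    segmented image as a whole.  Undefined statistics (zero variance, as in
    a constant image) are replaced by the sentinel 0 with a warning so
    feature tables stay rectangular.
    """
    indexed = quantize_levels(segmented, levels)
    glcm = compute_glcm(indexed, levels=levels, offset=offset, symmetric=symmetric)
    degenerate = glcm.degenerate
    if degenerate:
        # No pixel pairs: fall back to the single-level path (point-mass P).
        p = np.zeros((levels, levels))
        p[0, 0] = 1.0
    else:
        p = normalize_glcm(glcm)
    stats = cooc_stats(p)

    def _guard(fn, *args):
        nonlocal degenerate
        try:
            return fn(*args)
        except UndefinedStatisticError as exc:
            warnings.warn(f"{exc}; substituting 0", stacklevel=3)
            degenerate = True
            return None

    corr = _guard(correlation, p, stats)
    moments = _guard(entry_moments, p, stats)
    if moments is None:
        rms = float(np.sqrt((p ** 2).sum() / (levels - 1)))
        skew = kurt = None
    else:
        rms, skew, kurt = moments
    return FeatureVector(
        contrast=contrast(p),
        energy=energy(p),
        entropy=entropy(p),
        homogeneity=homogeneity(p),
        correlation=0.0 if corr is None else corr,
        rms=rms,
        skewness=0.0 if skew is None else skew,
        kurtosis=0.0 if kurt is None else kurt,
        glcm_mean=stats.mu_i,
        glcm_variance=stats.sigma_i ** 2,
        degenerate=degenerate,
    )


def extract_feature_table(
    segmented_images,
    labels,
    image_ids=None,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
):
    """Build the per-image feature table: 10 feature columns plus ``label``.

    Returns a pandas DataFrame with one row per image; ``image_id`` is the
    index when ids are given.
    """
    import pandas as pd

    rows = [extract_feature_vector(img, levels=levels, offset=offset).to_array()
            for img in segmented_images]
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table["label"] = np.asarray(labels, dtype=int)
    if image_ids is not None:
        table.index = pd.Index(image_ids, name="image_id")
    return table
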