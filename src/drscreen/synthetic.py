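"""Synthetic fundus phantoms and synthetic feature tables.

The phantom emulates the gross photometric structure of a fundus
photograph — a bright circular retinal disc with radial intensity falloff
on a dark surround, dark curvilinear vessel trees (each with the thin bright central light
reflex real vessels show) radiating from the centre, and, for the DR
class, yellow-white speckled exudate clusters plus small bright
microaneurysm-like dots — with additive Gaussian sensor noise.  It
is deliberately not photorealistic (no optic disc, no macula, no colour
pathology): it exists so the segmentation, texture and classification
operators can be exercised end-to-end with known ground truth.

All randomness flows from one master seed; per-image seeds are derived
with counter-based ``SeedSequence`` spawning so any subset regenerates
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _draw_disk

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "LabeledImageSet",
    "generate_fundus",
    "generate_dataset",
    "generate_feature_table",
]


@dataclass
class PhantomConfig:
    """Geometry and noise of the phantom.

    Defaults give a 512 px image whose disc fills ~90% of the frame,
    6-10 vessels of 2-3 px half-width and, for the DR class, 6-10 exudate
    clusters of 4-12 px extent plus 15-30 microaneurysm dots, with 2%
    Gaussian sensor noise — a lesion load typical of a screening-positive
    eye, so lesioned and healthy phantoms are texturally distinct by
    construction while single operators stay testable.
    """

    size: int = 512
    disc_radius_frac: float = 0.45
    vessel_count_range: tuple[int, int] = (6, 10)
    vessel_tortuosity: float = 0.25
    vessel_width_range: tuple[int, int] = (2, 3)
    lesion_count_range: tuple[int, int] = (6, 10)
    lesion_radius_range: tuple[int, int] = (4, 12)
    ma_count_range: tuple[int, int] = (15, 30)
    noise_sd: float = 0.02
    seed: int = 0


@dataclass
class GroundTruth:
    vessel_skeleton: np.ndarray          # bool mask of vessel centrelines
    lesion_centers: list = field(default_factory=list)
    ma_centers: list = field(default_factory=list)


@dataclass
class LabeledImageSet:
    images: list
    labels: np.ndarray                   # 0 = healthy, 1 = DR
    truths: list


def _disc_base(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Bright disc with quadratic radial falloff on a dark surround."""
    n = cfg.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    radius = cfg.disc_radius_frac * n
    base = np.full((n, n), 0.04)
    inside = r <= radius
    peak = rng.uniform(0.75, 0.82)
    base[inside] = peak * (1.0 - 0.5 * (r[inside] / radius) ** 2)
    return base


def _walk_vessel(cfg, rng, vessel_mask, reflex_mask, skeleton, cy, cx, radius):
    """Trace one tortuous radial walk, stamping the vessel body and its
    central light reflex (the thin bright stripe real vessels show along
    their axis) into boolean masks; the centreline is the ground truth."""
    n = cfg.size
    ang = rng.uniform(0, 2 * np.pi)
    pos = np.array([cy, cx]) + rng.normal(0, radius * 0.05, size=2)
    width = rng.integers(cfg.vessel_width_range[0], cfg.vessel_width_range[1] + 1)
    while True:
        y, x = pos
        if not (0 <= y < n and 0 <= x < n):
            break
        if np.hypot(y - cy, x - cx) > 0.95 * radius:
            break
        skeleton[int(round(y)), int(round(x))] = True
        rr, cc = _draw_disk((y, x), width + 1, shape=(n, n))
        vessel_mask[rr, cc] = True
        rr, cc = _draw_disk((y, x), 1, shape=(n, n))
        reflex_mask[rr, cc] = True
        ang += rng.normal(0, cfg.vessel_tortuosity)
        pos = pos + np.array([np.sin(ang), np.cos(ang)])


def generate_fundus(config: PhantomConfig, label: str, seed=None):
    """One phantom: RGB float image in [0, 1] plus its ground truth.

    ``label`` is ``"healthy"`` or ``"dr"``; DR phantoms carry speckled
    yellow-white exudate clusters (intensity above the disc background's
    90th percentile) and small bright dots, healthy ones carry none.  Bit-reproducible for
    a fixed (config, seed).
    """
    if label not in ("healthy", "dr"):
        raise ValueError(f"label must be 'healthy' or 'dr', got {label!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.size
    cy = cx = (n - 1) / 2.0
    radius = config.disc_radius_frac * n

    intensity = _disc_base(config, rng)
    skeleton = np.zeros((n, n), dtype=bool)
    vessel_mask = np.zeros((n, n), dtype=bool)
    reflex_mask = np.zeros((n, n), dtype=bool)
    n_vessels = rng.integers(config.vessel_count_range[0], config.vessel_count_range[1] + 1)
    for _ in range(n_vessels):
        _walk_vessel(config, rng, vessel_mask, reflex_mask, skeleton, cy, cx, radius)
    base = intensity.copy()
    # dark vessel body with a bright central light reflex along the axis
    intensity[vessel_mask] = base[vessel_mask] * rng.uniform(0.10, 0.18)
    intensity[reflex_mask] = base[reflex_mask]

    lesion_centers: list = []
    ma_centers: list = []
    lesion_mask = np.zeros((n, n), dtype=bool)
    if label == "dr":
        # exudate intensity sits above the 90th percentile of the disc interior
        yy, xx = np.mgrid[0:n, 0:n]
        inside = np.hypot(yy - cy, xx - cx) <= radius
        bright_floor = np.percentile(intensity[inside], 90)
        n_lesions = rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1)
        for _ in range(n_lesions):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.1, 0.8) * radius
            ly, lx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            extent = rng.uniform(*config.lesion_radius_range)
            # hard exudates deposit as a cluster of small bright specks, not
            # one smooth blob: each lesion scatters speckles over its extent
            n_spots = rng.integers(30, 60)
            for _ in range(n_spots):
                sy, sx = rng.normal((ly, lx), extent)
                rr, cc = _draw_disk((sy, sx), rng.uniform(1.5, 3.0), shape=(n, n))
                intensity[rr, cc] = np.clip(bright_floor * rng.uniform(1.1, 1.35), 0, 1)
                lesion_mask[rr, cc] = True
            lesion_centers.append((float(ly), float(lx)))
        n_ma = rng.integers(config.ma_count_range[0], config.ma_count_range[1] + 1)
        for _ in range(n_ma):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.05, 0.85) * radius
            my, mx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            rr, cc = _draw_disk((my, mx), rng.uniform(1.0, 2.0), shape=(n, n))
            intensity[rr, cc] = np.clip(bright_floor * rng.uniform(1.05, 1.2), 0, 1)
            ma_centers.append((float(my), float(mx)))

    intensity = np.clip(intensity + rng.normal(0, config.noise_sd, size=(n, n)), 0, 1)
    # fundus-like colour cast: strong red channel, weaker green, faint blue;
    # hard exudates are yellow-white (high green), unlike the orange retina
    green = np.where(lesion_mask, 0.90, 0.55)
    blue = np.where(lesion_mask, 0.35, 0.20)
    rgb = np.stack([intensity, intensity * green, intensity * blue], axis=-1)
    truth = GroundTruth(vessel_skeleton=skeleton, lesion_centers=lesion_centers,
                        ma_centers=ma_centers)
    return rgb, truth


def generate_dataset(n_per_class: int, config: PhantomConfig | None = None,
                     seed: int = 0) -> LabeledImageSet:
    """Balanced phantom set: ``n_per_class`` healthy then DR images.

    Per-image seeds are spawned deterministically from the master seed, so
    the same call always regenerates the identical set.
    """
    cfg = config or PhantomConfig()
    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    images, truths = [], []
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    for i, lab in enumerate(labels):
        img, truth = generate_fundus(cfg, "dr" if lab else "healthy", seed=children[i])
        images.append(img)
        truths.append(truth)
    return LabeledImageSet(images=images, labels=labels, truths=truths)


def generate_feature_table(n_per_class: int, effect_size_delta: float,
                           noise_sd: float = 1.0, seed: int = 0,
                           n_informative: int = 10):
    """Class-conditional Gaussian feature table for classifier tests.

    Ten feature columns; the first ``n_informative`` columns differ in
    class mean by ``effect_size_delta * noise_sd``.  Rows are shuffled;
    the returned DataFrame has the ten feature columns plus ``label``.
    """
    from drscreen.glcm import FEATURE_NAMES
    import pandas as pd

    rng = np.random.default_rng(seed)
    shift = np.zeros(10)
    shift[:n_informative] = effect_size_delta * noise_sd
    x0 = rng.normal(0.0, noise_sd, size=(n_per_class, 10))
    x1 = rng.normal(0.0, noise_sd, size=(n_per_class, 10)) + shift
    x = np.vstack([x0, x1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    order = rng.permutation(2 * n_per_class)
    table = pd.DataFrame(x[order], columns=list(FEATURE_NAMES))
    table["label"] = y[order]
    return table
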