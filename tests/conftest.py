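import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_pair():
    """One DR and one healthy phantom with ground truth (fixed seeds)."""
    from drscreen import PhantomConfig, generate_fundus

    cfg = PhantomConfig()
    dr_img, dr_truth = generate_fundus(cfg, "dr", seed=3)
    healthy_img, healthy_truth = generate_fundus(cfg, "healthy", seed=4)
    return {
        "dr": (dr_img, dr_truth),
        "healthy": (healthy_img, healthy_truth),
        "config": cfg,
    }


@pytest.fixture(scope="session")
def segmented_pair(phantom_pair):
    """Segmentation results for the fixture phantoms."""
    from drscreen import segment_fundus

    return {
        label: segment_fundus(phantom_pair[label][0])
        for label in ("dr", "healthy")
    }


def brute_force_glcm(indexed: np.ndarray, levels: int, offset) -> np.ndarray:
    """Independent pair-counting oracle: explicit double loop."""
    h, w = indexed.shape
    dr, dc = offset
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[indexed[r, c], indexed[r2, c2]] += 1
    return counts
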