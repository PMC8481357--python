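import math

import numpy as np
import pytest

from zorbkit.gmls import GMLSConfig, Neighborhood, weight


@pytest.fixture(scope="session")
def gmls4() -> GMLSConfig:
    return GMLSConfig(order=4)


def center_neighborhood(offsets: np.ndarray, eps: float) -> Neighborhood:
    """Neighborhood of the origin over the given offset cloud."""
    d = np.linalg.norm(offsets, axis=1)
    keep = (d > 0) & (d < eps)
    return Neighborhood(
        center_index=0,
        center=np.zeros(2),
        eps=eps,
        neighbor_indices=np.flatnonzero(keep),
        positions=offsets[keep],
        distances=d[keep],
        weights=weight(d[keep], eps),
    )


def grid_offsets(n: int, h: float) -> np.ndarray:
    g = np.mgrid[-n:n + 1, -n:n + 1].reshape(2, -1).T * float(h)
    return g


def disk_fixture(
    radii_px=(15, 18, 22),
    centers=((80, 90), (250, 100), (170, 260)),
    shape=(360, 360),
    background=210.0,
    contrast=100.0,
    noise_sd=10.0,
    seed=0,
    inverted=False,
):
    """Sharp dark disks on a bright noisy background, with ground truth."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, background)
    truth = []
    for (cx, cy), r in zip(centers, radii_px):
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        img -= contrast / (1 + np.exp(np.clip((d - r) / 0.5, -50, 50)))
        truth.append({"center": (cx, cy), "radius": r,
                      "area": math.pi * r * r})
    img += rng.normal(0, noise_sd, shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    if inverted:
        img = (255 - img).astype(np.uint8)
    return img, truth
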