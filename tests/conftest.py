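import numpy as np
import pytest
from scipy import ndimage

import epidtrack as et


def random_rectilinear_mask(rng: np.random.Generator, shape=(128, 128)) -> np.ndarray:
    """Union of 1-4 overlapping axis-aligned rectangles, holes filled.

    All rectangles intersect a base rectangle so the union is a single
    connected region; minimum side length 3 px avoids 1-px spurs that
    would make the boundary polygon non-simple.
    """
    H, W = shape
    while True:
        r0 = rng.integers(10, H // 2)
        c0 = rng.integers(10, W // 2)
        h0 = rng.integers(8, H // 3)
        w0 = rng.integers(8, W // 3)
        mask = np.zeros(shape, dtype=bool)
        mask[r0 : r0 + h0, c0 : c0 + w0] = True
        for _ in range(rng.integers(0, 4)):
            rr = rng.integers(r0, r0 + h0 - 3)
            cc = rng.integers(c0, c0 + w0 - 3)
            hh = rng.integers(3, H // 3)
            ww = rng.integers(3, W // 3)
            mask[rr : min(rr + hh, H - 2), cc : min(cc + ww, W - 2)] = True
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        if n >= 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = ndimage.binary_fill_holes(labels == (np.argmax(sizes) + 1))
            if mask.sum() >= 16:
                return mask


@pytest.fixture(scope="session")
def geometry_512() -> et.GeometryConfig:
    return et.GeometryConfig(matrix_size=512)


@pytest.fixture(scope="session")
def clean_series_512(geometry_512):
    """Noise-free 21-frame phantom-style scene with a constant offset."""
    cfg = et.default_scene(n_frames=21, tracking_offset=(0.5, -0.3))
    images, truth = et.render_series(cfg, geometry_512)
    metadata = et.SeriesMetadata(geometry=geometry_512)
    return images, truth, metadata
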