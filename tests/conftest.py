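import numpy as np
import pytest

from plaquant import UVImage, default_scene, render_scene


def classify_loop(image, mask, delta, l):
    """Independent per-pixel oracle for the dental-pixel partition:
    VISIBLE (1) for G-B > 0; NV1 (2) for delta <= G-B <= 0; NV2 (3) for
    l <= G-B < delta; NONPLAQUE (4) otherwise, including pixels with a
    zero green or blue channel; OUTSIDE (0) off the mask."""
    H, W = mask.shape
    out = np.zeros((H, W), dtype=np.uint8)
    rows_m = mask.tolist()
    rows_g = image.pixels[..., 1].astype(int).tolist()
    rows_b = image.pixels[..., 2].astype(int).tolist()
    for y in range(H):
        mr, gr, br, orow = rows_m[y], rows_g[y], rows_b[y], out[y]
        for x in range(W):
            if not mr[x]:
                continue
            g, b = gr[x], br[x]
            v = g - b
            if v > 0:
                orow[x] = 1
            elif g > 0 and b > 0:
                if v >= delta:
                    orow[x] = 2
                elif v >= l:
                    orow[x] = 3
                else:
                    orow[x] = 4
            else:
                orow[x] = 4
    return out


def random_uv_image(rng, shape=(64, 64)):
    px = rng.integers(0, 256, size=shape + (3,), dtype=np.uint8)
    return UVImage(px)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def clean_scene():
    """One rendered frontal-view scene without plaque."""
    return render_scene(default_scene(seed=11, n_teeth=4))


@pytest.fixture
def plaque_scene():
    """One rendered scene with 30% plaque coverage on every tooth."""
    return render_scene(default_scene(seed=12, n_teeth=4, coverage=0.3))
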