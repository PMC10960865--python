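"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by the most literal
route available (per-pixel sorted windows, explicit rank enumeration) and
never call the library code paths they are used to check.
"""

import numpy as np
import pytest

from punctatrack import FluorescenceImage, RoiMask


def brute_median_ratio(data: np.ndarray, window: int) -> np.ndarray:
    """Literal per-pixel median-ratio: symmetric padding, sorted windows.

    The window anchor is the centre pixel for odd windows and the
    upper-left pixel of the central 2x2 block for even windows; of the
    w*w sorted values the element at rank w*w//2 is taken (the upper of
    the two middle elements when w*w is even). Division floor matches the
    library convention (1e-6 of the image maximum).
    """
    w = window
    lo = (w - 1) // 2
    pad = np.pad(data, w, mode="symmetric")
    med = np.empty_like(data, dtype=float)
    h, wd = data.shape
    for i in range(h):
        for j in range(wd):
            win = pad[i + w - lo : i + 2 * w - lo, j + w - lo : j + 2 * w - lo]
            med[i, j] = np.sort(win.ravel())[w * w // 2]
    floor = 1e-6 * data.max()
    return data / np.maximum(med, floor)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_image(rng):
    """Random 24x24 image with a full-frame cytosol mask."""
    data = rng.uniform(10, 100, size=(24, 24))
    return FluorescenceImage(data), RoiMask(np.ones((24, 24), dtype=bool), "cytosol")
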