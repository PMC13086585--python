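import numpy as np
import pytest

from fa_screenkit.datatypes import FieldImage


def gaussian_nucleus_image(shape, centers, peak=8000.0, sigma=6.0,
                           background=0.0):
    """Sharp synthetic nucleus channel: sum of Gaussian blobs."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, float(background))
    for r, c in centers:
        img += peak * np.exp(-((rr - r) ** 2 + (cc - c) ** 2)
                             / (2 * sigma ** 2))
    return img


def rect_image(shape, rects, value=1000.0, background=0.0):
    """Image with axis-aligned rectangles of the given value."""
    img = np.full(shape, float(background))
    for r0, c0, h, w in rects:
        img[r0:r0 + h, c0:c0 + w] = value
    return img


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


@pytest.fixture
def simple_field():
    """Field with two 100-px FA squares, one 10-px speck, four nuclei."""
    fa = rect_image((200, 200), [(30, 30, 10, 10), (30, 120, 10, 10)],
                    value=3000.0)
    fa[150:152, 150:155] = 3000.0  # 10-px speck
    nuc = gaussian_nucleus_image(
        (200, 200), [(50, 50), (50, 150), (150, 50), (150, 150)])
    return FieldImage(channels={"fa": fa, "nucleus": nuc})
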