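import numpy as np
import pytest

from woundscreen.layout import default_layout
from woundscreen.synthetic import ImageSpec, WoundTruth, generate_wound_pair

# nominal scratch: 0.38 x 3.8 mm at 2.97 um/px ~ 128 x 1280 px
WOUND_RECT = (128, 128, 256, 1408)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free two-level imaging spec: the exact-oracle regime."""
    return ImageSpec(384, 1536, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_spec():
    return ImageSpec(384, 1536, noise_sd=40.0, seed=12)


@pytest.fixture(scope="session")
def clean_half_closed_pair(clean_spec):
    truth = WoundTruth(WOUND_RECT, closure_fraction=0.5)
    return generate_wound_pair(clean_spec, truth)


def true_masks(spec, truth):
    """Reconstruct the exact boolean cell mask of both timepoints from a
    filled-in wound truth (independent of the rendered images)."""
    a0_free = np.zeros(spec.shape, dtype=bool)
    r0, c0, r1, c1 = truth.wound_rect_px
    a0_free[r0:r1, c0:c1] = True
    for tr0, tc0, tr1, tc1 in truth.tear_rects:
        a0_free[tr0:tr1, tc0:tc1] = True
    a24_free = np.zeros(spec.shape, dtype=bool)
    nr0, nc0, nr1, nc1 = truth.a24_rect_px
    a24_free[nr0:nr1, nc0:nc1] = True
    for dr0, dc0, dr1, dc1 in truth.debris_rects:
        a24_free[dr0:dr1, dc0:dc1] = False
    return ~a0_free, ~a24_free
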