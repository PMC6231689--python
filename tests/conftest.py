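import numpy as np
import pytest
from scipy.spatial.distance import cdist

from apomap import SyntheticEmbryoSpec, generate_embryo_image


@pytest.fixture(scope="session")
def small_spec():
    """A compact embryo (6 boundary stripes) used by most image tests."""
    return SyntheticEmbryoSpec(
        image_height_px=200,
        image_width_px=420,
        n_segments=6,
        event_count=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_embryo(small_spec):
    return generate_embryo_image(small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, midline-free embryo, sparse enough that no two event disks
    overlap (exact-recovery preconditions)."""
    return SyntheticEmbryoSpec(
        image_height_px=200,
        image_width_px=420,
        n_segments=6,
        event_count=25,
        noise_sd=0.0,
        midline_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_embryo(clean_spec):
    return generate_embryo_image(clean_spec)


def brute_force_distance(x, y, stripe_coords):
    """Exhaustive minimum Euclidean distance from (x, y) to any skeleton pixel.

    Independent oracle for the k-d tree nearest-pixel query: scans every pixel
    of the stripe.  ``stripe_coords`` is (N, 2) in (row, col) order.
    """
    pts = stripe_coords[:, ::-1].astype(float)  # -> (x, y)
    return float(cdist([[x, y]], pts).min())
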