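import numpy as np
import pytest
from hypothesis import settings

from cinemorph import LabelMask, PhantomParams, generate_phantom_series

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def stacked_la_lv():
    """LA rectangle directly above an LV rectangle, 1 mm/px."""
    grid = np.zeros((20, 40), dtype=int)
    grid[0:10, 5:35] = 2  # LA
    grid[10:20, 5:35] = 1  # LV
    return LabelMask(grid, (1.0, 1.0), {"LV": 1, "LA": 2})


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom series with truth."""
    return generate_phantom_series(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with mild boundary noise."""
    return generate_phantom_series(
        PhantomParams(seed=7, boundary_noise_sd_px=0.5)
    )


def brute_force_endpoints(pixels, spacing):
    """Independent exhaustive max-pairwise-distance search over band pixels.

    Returns the lexicographically smallest sorted pixel pair achieving the
    maximal mm-scaled Euclidean distance.
    """
    pts = np.asarray(pixels, dtype=float) * np.asarray(spacing)
    best = -1.0
    best_pair = None
    as_tuples = [tuple(int(v) for v in p) for p in pixels]
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.hypot(*(pts[i] - pts[j])))
            pair = tuple(sorted((as_tuples[i], as_tuples[j])))
            if d > best + 1e-12 or (
                abs(d - best) <= 1e-12 and (best_pair is None or pair < best_pair)
            ):
                best = d
                best_pair = pair
    if best_pair is None:
        return as_tuples[0], as_tuples[0], 0.0
    return best_pair[0], best_pair[1], best
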