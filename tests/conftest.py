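import numpy as np
import pytest

from flagtrace import PhantomParams, make_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """Single frame with a straight (zero-amplitude) flagellum."""
    params = PhantomParams(n_frames=1, wave_amplitude_px=0.0)
    frames, truth = make_phantom(params)
    return params, frames, truth


@pytest.fixture(scope="session")
def beating_phantom():
    """Short sinusoidal stack (12 frames) for per-frame unit tests."""
    params = PhantomParams(n_frames=12)
    frames, truth = make_phantom(params)
    return params, frames, truth


@pytest.fixture(scope="session")
def halfwidth3_phantom():
    """Straight flagellum of half-width 3 for distance-oracle checks."""
    params = PhantomParams(
        n_frames=1, wave_amplitude_px=0.0, flagellum_halfwidth_px=3.0
    )
    frames, truth = make_phantom(params)
    return params, frames, truth


def brute_force_distance_map(mask: np.ndarray) -> np.ndarray:
    """O(N^2) exact nearest-background Euclidean distance (test oracle)."""
    from scipy.spatial.distance import cdist

    out = np.zeros(mask.shape, dtype=float)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if len(fg) == 0 or len(bg) == 0:
        return out
    out[fg[:, 0], fg[:, 1]] = cdist(fg, bg).min(axis=1)
    return out


def random_blob_mask(rng: np.random.Generator, shape=(32, 32), p=0.45) -> np.ndarray:
    """Random binary mask with blob-like structure (closing of noise)."""
    from scipy import ndimage

    return ndimage.binary_closing(rng.random(shape) < p)
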