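import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from hsunmix import (
    HyperspectralCube,
    Modality,
    Phantom,
    default_axis,
    make_spectra,
)


@pytest.fixture
def small_axis():
    """Coarse CH-stretch axis (19 points) for fast tests."""
    return default_axis(2650.0, 3100.0, 25.0)


@pytest.fixture
def lowrank_phantom():
    """Factory for a low-rank phantom whose components are all spatially
    widespread (smooth blob maps), suitable for SVD masking tests."""

    def _make(ny=30, nx=30, k=2, noise_sigma=0.01, seed=5, axis=None):
        rng = np.random.default_rng(seed)
        axis = axis or default_axis()
        maps = []
        for _ in range(k):
            f = gaussian_filter(rng.normal(size=(ny, nx)), 4.0)
            maps.append(f - f.min() + 0.05)
        C = np.stack(maps).reshape(k, -1).T
        C /= C.sum(1, keepdims=True)
        S = make_spectra(k, axis, seed=seed)
        data = C @ S.T
        if noise_sigma > 0:
            data = data + rng.normal(0, noise_sigma, data.shape)
        cube = HyperspectralCube(
            np.clip(data, 0, None).reshape(ny, nx, len(axis)),
            axis,
            Modality.SUSCEPTIBILITY_IMAG,
        )
        return Phantom(C, S, cube, noise_sigma, seed)

    return _make


def matched_spectral_rms(S_rec: np.ndarray, refs: list[np.ndarray]) -> float:
    """Worst-component RMS deviation under the best column permutation."""
    from itertools import permutations

    k = len(refs)
    assert S_rec.shape[1] == k
    best = np.inf
    for perm in permutations(range(k)):
        dev = max(
            float(np.sqrt(np.mean((S_rec[:, perm[j]] - refs[j]) ** 2)))
            for j in range(k)
        )
        best = min(best, dev)
    return best
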