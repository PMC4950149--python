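"""Synthetic phantoms with the statistical structure the analysis assumes.

The generators build ground-truth component spectra (sums of Lorentzian
bands in the CH-stretch region), non-negative spatially structured
concentration maps whose rows sum to one (a filled volume), and additive
Gaussian noise of constant standard deviation — the regime obtained for
CARS after the square-root transform of the intensity, or directly for
SRS/Raman data.  Two experiment protocols are reproduced:

* a homogeneous single-substance image in which exactly one pixel is
  replaced by a two-substance mixture ``(1−f)·A + f·B`` — the hardest
  case for a global-error factorization, used to probe how small a
  localized admixture the weighted algorithm still recovers;
* sparse high-amplitude spikes over short spectral runs, emulating
  objects (e.g. bacteria) moving through the field of view during a
  sequential spectral acquisition.

Everything is deterministic given the seed, and every phantom carries its
ground truth so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_cube import HyperspectralCube, Modality, SpectralAxis

__all__ = [
    "Phantom",
    "default_axis",
    "SUBSTANCE_A_BANDS",
    "SUBSTANCE_B_BANDS",
    "make_spectra",
    "make_modified_pixel_phantom",
    "make_cell_phantom",
    "add_spikes",
]

#: Surrogate band sets (center cm⁻¹, FWHM cm⁻¹, amplitude) for two lipids
#: differing mainly in the =C–H stretch near 3010 cm⁻¹ (unsaturation):
#: substance A mimics a saturated fatty acid (octanoic-acid-like),
#: substance B an unsaturated one (linoleic-acid-like).  The exact shapes
#: are free parameters of the phantom, not claims about real substances.
SUBSTANCE_A_BANDS: tuple[tuple[float, float, float], ...] = (
    (2850.0, 30.0, 1.0),
    (2880.0, 35.0, 0.70),
    (2930.0, 45.0, 0.50),
    (3010.0, 25.0, 0.05),
)
SUBSTANCE_B_BANDS: tuple[tuple[float, float, float], ...] = (
    (2850.0, 30.0, 0.70),
    (2880.0, 35.0, 0.55),
    (2930.0, 45.0, 0.60),
    (3010.0, 25.0, 0.65),
)


def default_axis(lo: float = 2650.0, hi: float = 3100.0, step: float = 5.0) -> SpectralAxis:
    """CH-stretch wavenumber axis, 2650–3100 cm⁻¹ in 5 cm⁻¹ steps."""
    return SpectralAxis(np.arange(lo, hi + step / 2, step))


@dataclass
class Phantom:
    """A synthetic cube together with its generating ground truth."""

    truth_C: np.ndarray  # P × k volume fractions
    truth_S: np.ndarray  # S × k non-negative spectra (max-normalized)
    cube: HyperspectralCube
    noise_sigma: float
    seed: int
    spike_mask: np.ndarray | None = None  # P × S boolean, True at spiked entries

    @property
    def matrix(self) -> np.ndarray:
        """The flattened P × S data (row-major), as the algorithms see it."""
        ny, nx, S = self.cube.shape
        return self.cube.data.reshape(ny * nx, S)


def lorentzian(x: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Lorentzian band with peak ``amplitude`` and full width ``fwhm``."""
    return amplitude / (1.0 + ((np.asarray(x, float) - center) / (fwhm / 2.0)) ** 2)


def make_spectra(
    k: int,
    axis: SpectralAxis,
    bands: Sequence[Sequence[tuple[float, float, float]]] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Build ``k`` non-negative component spectra as sums of Lorentzians.

    ``bands`` gives one band list per component; if omitted, bands are
    drawn deterministically from ``seed`` with main peaks spread across
    the axis so the components are spectrally distinct.  Each column is
    max-normalized to 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w = axis.wavenumbers
    if bands is None:
        rng = np.random.default_rng(seed)
        lo, hi = w[0], w[-1]
        centers = np.linspace(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo), k)
        bands = []
        for c in centers:
            blist = [(float(c + rng.normal(0, 5)), float(rng.uniform(20, 45)), 1.0)]
            for _ in range(rng.integers(2, 4)):
                blist.append(
                    (
                        float(rng.uniform(lo + 30, hi - 30)),
                        float(rng.uniform(20, 60)),
                        float(rng.uniform(0.1, 0.6)),
                    )
                )
            bands.append(blist)
    if len(bands) != k:
        raise ValueError(f"need {k} band lists, got {len(bands)}")
    S = np.zeros((w.size, k))
    for j, blist in enumerate(bands):
        for center, fwhm, amp in blist:
            if not (w[0] <= center <= w[-1]):
                raise ValueError(f"band center {center} outside axis range")
            S[:, j] += lorentzian(w, center, fwhm, amp)
        peak = S[:, j].max()
        if peak <= 0:
            raise ValueError(f"component {j} has a non-positive spectrum")
        S[:, j] /= peak
    return S


def make_modified_pixel_phantom(
    ny: int = 50,
    nx: int = 55,
    f: float = 0.5,
    noise_sigma: float = 0.01,
    seed: int = 0,
    axis: SpectralAxis | None = None,
    modified_pixel: tuple[int, int] | None = None,
) -> Phantom:
    """Homogeneous substance-A image with one two-substance mixed pixel.

    Every pixel carries the pure substance-A spectrum except one pixel
    (the image center by default) carrying ``(1−f)·A + f·B``.  Gaussian
    noise of standard deviation ``noise_sigma`` (in units of the peak
    spectral amplitude, which is 1) is added to every entry and the
    result clipped at zero.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    axis = axis or default_axis()
    truth_S = make_spectra(2, axis, [SUBSTANCE_A_BANDS, SUBSTANCE_B_BANDS])
    P = ny * nx
    truth_C = np.zeros((P, 2))
    truth_C[:, 0] = 1.0
    y, x = modified_pixel if modified_pixel is not None else (ny // 2, nx // 2)
    p = y * nx + x
    truth_C[p] = (1.0 - f, f)
    rng = np.random.default_rng(seed)
    clean = (truth_C @ truth_S.T).reshape(ny, nx, len(axis))
    data = clean + rng.normal(0.0, noise_sigma, clean.shape) if noise_sigma > 0 else clean
    cube = HyperspectralCube(
        np.clip(data, 0.0, None),
        axis,
        Modality.SUSCEPTIBILITY_IMAG,
        {"protocol": "modified-pixel", "f": f, "modified_pixel": [int(y), int(x)]},
    )
    return Phantom(truth_C, truth_S, cube, noise_sigma, seed)


def make_cell_phantom(
    ny: int = 40,
    nx: int = 40,
    k: int = 3,
    blob_sigma: float = 4.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    axis: SpectralAxis | None = None,
    minority_fraction: float = 0.015,
) -> Phantom:
    """Cell-like phantom: smooth blob concentration maps plus one minority
    component confined to fewer than 2% of the pixels.

    The majority maps are low-pass-filtered random fields (blob scale
    ``blob_sigma`` pixels); the last component occupies a small disc,
    exercising exactly the regime the spatial weighting is built for.
    Rows of ``truth_C`` sum to 1 (filled volume); with ``noise_sigma=0``
    the cube equals ``C·Sᵀ`` exactly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    from scipy.ndimage import gaussian_filter

    axis = axis or default_axis()
    rng = np.random.default_rng(seed)
    P = ny * nx
    maps = np.zeros((k, ny, nx))
    for j in range(k - 1):
        field = gaussian_filter(rng.normal(size=(ny, nx)), blob_sigma)
        field -= field.min()
        maps[j] = field + 0.05  # keep every pixel filled
    # minority component: a disc covering < minority_fraction of pixels
    radius = max(1.0, np.sqrt(minority_fraction * P / np.pi) - 0.5)
    cy, cx = rng.integers(ny // 4, 3 * ny // 4), rng.integers(nx // 4, 3 * nx // 4)
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    maps[k - 1][disc] = 0.8 * maps[:-1].sum(axis=0)[disc]
    C = maps.reshape(k, P).T
    C /= C.sum(axis=1, keepdims=True)
    truth_S = make_spectra(k, axis, seed=seed)
    clean = (C @ truth_S.T).reshape(ny, nx, len(axis))
    data = clean + rng.normal(0.0, noise_sigma, clean.shape) if noise_sigma > 0 else clean
    cube = HyperspectralCube(
        np.clip(data, 0.0, None),
        axis,
        Modality.SUSCEPTIBILITY_IMAG,
        {"protocol": "cell-blobs", "minority_pixels": int(disc.sum())},
    )
    return Phantom(C, truth_S, cube, noise_sigma, seed)


def add_spikes(
    phantom: Phantom, n_events: int, amplitude: float, seed: int = 0
) -> Phantom:
    """Inject motion-artifact-like spikes into a phantom.

    Each event increments a contiguous run of 1–5 spectral points at one
    random pixel by ``amplitude``; ``spike_mask`` records exactly the
    altered entries.  Unspiked entries are left bit-for-bit unchanged.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng(seed)
    ny, nx, S = phantom.cube.shape
    P = ny * nx
    data = phantom.cube.data.reshape(P, S).copy()
    mask = (
        phantom.spike_mask.copy()
        if phantom.spike_mask is not None
        else np.zeros((P, S), dtype=bool)
    )
    for _ in range(n_events):
        p = int(rng.integers(P))
        start = int(rng.integers(S))
        run = min(int(rng.integers(1, 6)), S - start)
        data[p, start : start + run] += amplitude
        mask[p, start : start + run] = True
    cube = HyperspectralCube(
        data.reshape(ny, nx, S),
        phantom.cube.axis,
        phantom.cube.modality,
        {**phantom.cube.meta, "spiked_events": n_events},
    )
    return replace(phantom, cube=cube, spike_mask=mask)
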