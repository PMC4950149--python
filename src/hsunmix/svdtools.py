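"""SVD decomposition, noise filtering, and iterative outlier masking.

The singular value decomposition of the (variance-stabilized) data
matrix separates a small number of structured spectral components from a
noise floor of near-equal singular values.  Truncating to the structured
components denoises the data; comparing the measurement with its
low-rank reconstruction exposes outliers — e.g. motion artifacts from
objects passing through the field during a sequential acquisition —
which are then masked and inpainted from the low-rank model in an
iterative loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SVDModel", "MaskResult", "svd_filter", "count_significant", "mask_outliers"]


@dataclass
class SVDModel:
    """SVD of a ``P × S`` data matrix in spectral orientation.

    ``left_spectra`` holds the singular *spectra* (length-``S`` columns,
    the spectral basis used for denoising and sparse reconstruction),
    ``right_vectors`` the spatial coefficients.
    """

    left_spectra: np.ndarray  # S × r orthonormal columns
    singular_values: np.ndarray  # r, non-increasing
    right_vectors: np.ndarray  # P × r orthonormal columns

    @classmethod
    def from_matrix(cls, D: np.ndarray) -> "SVDModel":
        u, s, vt = np.linalg.svd(np.asarray(D, float).T, full_matrices=False)
        return cls(left_spectra=u, singular_values=s, right_vectors=vt.T)

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Rank-``k`` (default: full) reconstruction, back in P × S shape."""
        k = self.singular_values.size if k is None else k
        u = self.left_spectra[:, :k]
        s = self.singular_values[:k]
        v = self.right_vectors[:, :k]
        return (v * s) @ u.T


@dataclass
class MaskResult:
    """Outcome of the iterative SVD outlier masking.

    ``cleaned`` equals the input everywhere outside ``outlier_mask`` and
    the low-rank reconstruction at masked entries; ``filtered`` is the
    final SVD-filtered matrix ``D_i*`` itself.
    """

    cleaned: np.ndarray
    filtered: np.ndarray
    outlier_mask: np.ndarray
    iterations: int
    threshold_xi: float
    stop_fraction: float
    converged: bool


def svd_filter(D: np.ndarray, k: int) -> np.ndarray:
    """Best rank-``k`` approximation of ``D`` (truncated SVD)."""
    D = np.asarray(D, float)
    r = min(D.shape)
    if not 1 <= k <= r:
        raise ValueError(f"k={k} outside [1, {r}]")
    u, s, vt = np.linalg.svd(D, full_matrices=False)
    return (u[:, :k] * s[:k]) @ vt[:k]


def count_significant(
    singular_values: np.ndarray,
    factor: float = 3.0,
    override: int | None = None,
) -> int:
    """Number of leading singular values above the noise floor.

    The floor is estimated as ``factor`` times the median of the trailing
    half of the singular-value spectrum (the part dominated by noise);
    ``override`` bypasses the estimate entirely.
    """
    if override is not None:
        return int(override)
    s = np.asarray(singular_values, float)
    if np.any(np.diff(s) > 1e-12 * s[0]):
        raise ValueError("singular values must be sorted non-increasing")
    if s.size < 4:
        raise ValueError("automatic estimation needs at least 4 singular values")
    floor = factor * np.median(s[s.size // 2 :])
    return int(np.searchsorted(-s, -floor))  # count of s > floor


def mask_outliers(
    D0: np.ndarray,
    k: int | None = None,
    xi: float = 3.0,
    f: float = 0.01,
    max_iter: int = 50,
) -> MaskResult:
    """Iteratively mask entries whose residual against a rank-``k`` model
    exceeds ``xi`` times the RMS residual, and inpaint them.

    Starting from the measurement ``D0``, each iteration SVD-filters the
    current matrix to rank ``k`` and rebuilds the next iterate entrywise:
    the original value where the absolute residual ``|D0 − D_i*|`` stays
    below ``xi·‖D0 − D_i*‖_F/√(S·P)``, the filtered value otherwise.  The
    loop stops when the number of entries changing masking state drops
    below a fraction ``f`` of the masked entries (or the mask is empty)
    *and* the residual norm has become stationary — on small images the
    count condition alone can trigger during a zero-change plateau while
    the inpainted values are still relaxing toward the low-rank model.
    Ties at the threshold keep the original value.
    """
    D0 = np.asarray(D0, float)
    if not np.all(np.isfinite(D0)):
        raise ValueError("input contains non-finite values")
    if xi <= 0:
        raise ValueError("xi must be positive")
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    if k is None:
        k = max(1, count_significant(np.linalg.svd(D0, compute_uv=False)))
    P, S = D0.shape
    Di = D0
    prev_mask = np.zeros(D0.shape, dtype=bool)
    prev_norm = np.inf
    converged = False
    mask = prev_mask
    Dstar = D0
    for it in range(1, max_iter + 1):
        Dstar = svd_filter(Di, k)
        resid = np.abs(D0 - Dstar)
        resid_norm = float(np.linalg.norm(D0 - Dstar))
        if resid_norm <= 1e-12 * np.linalg.norm(D0):
            # the low-rank model already reproduces the data
            mask = np.zeros(D0.shape, dtype=bool)
            converged = True
            break
        thr = xi * resid_norm / np.sqrt(S * P)
        mask = resid > thr
        Di = np.where(mask, Dstar, D0)
        n_excluded = int(mask.sum())
        if n_excluded == 0:
            converged = True
            break
        n_changed = int((mask ^ prev_mask).sum())
        norm_stationary = abs(resid_norm - prev_norm) <= 1e-4 * max(resid_norm, 1e-300)
        if n_changed < f * n_excluded and norm_stationary:
            converged = True
            break
        prev_mask = mask
        prev_norm = resid_norm
    return MaskResult(
        cleaned=np.where(mask, Dstar, D0),
        filtered=Dstar,
        outlier_mask=mask,
        iterations=it,
        threshold_xi=xi,
        stop_fraction=f,
        converged=converged,
    )
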