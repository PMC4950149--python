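"""Sparse spectral sampling: design, conditioning, and reconstruction.

Sequential hyperspectral acquisition spends most of its time measuring
spectral points that carry little independent information.  If a pilot
image (few spatial points, full spectral resolution) shows that only
``S′`` singular spectra stand above the noise, the full image can be
acquired at just ``S′`` well-chosen spectral positions and the complete
spectra reconstructed linearly:

    D_rec = ũ · û⁻¹ · D

where ``ũ`` (``S × S′``) holds the first ``S′`` singular spectra and
``û`` (``S′ × S′``) their restriction to the selected positions.  The
selection minimizes the noise amplification ``‖û⁻¹‖_F²`` by a random
walk over index subsets (exhaustive search when feasible).  Before the
inversion, the restricted columns are Gram–Schmidt-orthogonalized (no
renormalization) in order of decreasing singular value, with identical
column operations applied to ``ũ`` so the unfiltered reconstruction is
unchanged; the row norms of ``û⁻¹`` then read directly as per-component
noise gains, and components whose gain exceeds ``ξ`` times that of the
most significant component are discarded by zeroing their row.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .fsc3 import spectral_error_map

__all__ = [
    "SamplingDesign",
    "design_sampling",
    "build_operator",
    "reconstruct",
    "sparse_error_map",
]

#: Condition-number limit above which the restricted basis is treated as
#: numerically singular.
COND_LIMIT = 1e12

#: Subset-space size up to which the design search is exhaustive.
EXHAUSTIVE_LIMIT = 100_000


@dataclass
class SamplingDesign:
    """A set of spectral positions with its conditioned reconstruction
    operator and per-component noise gains."""

    indices: np.ndarray  # S′ sorted spectral indices
    u_tilde: np.ndarray  # S × S′ (column-conditioned) singular spectra
    u_hat: np.ndarray  # S′ × S′ restricted, Gram–Schmidt-conditioned
    inv_filtered: np.ndarray  # û⁻¹ with rejected rows zeroed
    row_norms: np.ndarray  # per-component noise gains ‖row_m(û⁻¹)‖
    xi: float
    rejected: np.ndarray  # boolean per component

    @property
    def s_prime(self) -> int:
        return int(self.indices.size)


def _noise_gain(u: np.ndarray, indices, s_prime: int) -> float:
    """Total white-noise amplification ‖û⁻¹‖_F² of a candidate subset."""
    uhat = u[np.asarray(indices), :s_prime]
    try:
        inv = np.linalg.inv(uhat)
    except np.linalg.LinAlgError:
        return np.inf
    if not np.all(np.isfinite(inv)):
        return np.inf
    return float(np.sum(inv**2))


def design_sampling(
    u: np.ndarray,
    s_prime: int,
    n_steps: int | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    method: str = "auto",
) -> np.ndarray:
    """Choose ``S′`` spectral indices minimizing the total noise gain.

    ``method='auto'`` enumerates all subsets when there are at most
    ``EXHAUSTIVE_LIMIT`` of them and otherwise runs a seeded random walk
    (single-index swap proposals, accepted only on strict improvement,
    with restarts).  Returns the sorted index array; combine with
    :func:`build_operator` to obtain the reconstruction operator.
    """
    u = np.asarray(u, float)
    S, r = u.shape
    if not 1 <= s_prime <= min(r, S):
        raise ValueError(f"s_prime={s_prime} outside [1, {min(r, S)}]")
    n_subsets = math.comb(S, s_prime)
    if method not in {"auto", "exhaustive", "walk"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "exhaustive" or (method == "auto" and n_subsets <= EXHAUSTIVE_LIMIT):
        best, best_obj = None, np.inf
        for comb in itertools.combinations(range(S), s_prime):
            obj = _noise_gain(u, comb, s_prime)
            if obj < best_obj:
                best, best_obj = comb, obj
        if best is None or not np.isfinite(best_obj):
            raise np.linalg.LinAlgError(
                "every restriction is singular; increase s_prime or the pilot rank"
            )
        return np.asarray(best, dtype=int)

    n_steps = n_steps if n_steps is not None else 2000 * s_prime
    rng = np.random.default_rng(seed)
    best, best_obj = None, np.inf
    for _ in range(n_restarts):
        idx = rng.choice(S, size=s_prime, replace=False)
        obj = _noise_gain(u, idx, s_prime)
        tries = 0
        while not np.isfinite(obj) and tries < 100:
            idx = rng.choice(S, size=s_prime, replace=False)
            obj = _noise_gain(u, idx, s_prime)
            tries += 1
        if not np.isfinite(obj):
            continue
        selected = set(idx.tolist())
        for _ in range(n_steps):
            out_i = int(rng.integers(s_prime))
            candidates = np.setdiff1d(np.arange(S), idx, assume_unique=False)
            new = int(candidates[rng.integers(candidates.size)])
            proposal = idx.copy()
            proposal[out_i] = new
            new_obj = _noise_gain(u, proposal, s_prime)
            if new_obj < obj:
                idx, obj = proposal, new_obj
                selected = set(idx.tolist())
        if obj < best_obj:
            best, best_obj = np.sort(idx), obj
    if best is None:
        raise np.linalg.LinAlgError(
            "random walk found no invertible restriction; increase s_prime"
        )
    return np.asarray(best, dtype=int)


def _gram_schmidt_pair(u_hat: np.ndarray, u_tilde: np.ndarray):
    """Orthogonalize û's columns (no renormalization) in their given
    order, applying the identical elementary column operations to ũ."""
    uh = u_hat.copy()
    ut = u_tilde.copy()
    n = uh.shape[1]
    for m in range(1, n):
        for l in range(m):
            denom = float(uh[:, l] @ uh[:, l])
            if denom <= 0:
                raise np.linalg.LinAlgError("restricted basis is singular")
            coef = float(uh[:, l] @ uh[:, m]) / denom
            uh[:, m] = uh[:, m] - coef * uh[:, l]
            ut[:, m] = ut[:, m] - coef * ut[:, l]
    return uh, ut


def build_operator(
    u: np.ndarray,
    indices: np.ndarray,
    s_prime: int | None = None,
    xi: float = math.sqrt(2.0),
) -> SamplingDesign:
    """Build the conditioned reconstruction operator for a given index set.

    Restricts the first ``S′`` singular spectra to the selected rows,
    Gram–Schmidt-conditions the columns in decreasing-singular-value
    order (mirrored on ``ũ`` so the unfiltered product ``ũ·û⁻¹`` is
    invariant), inverts, and zeroes the rows of ``û⁻¹`` whose norm —
    the component's noise gain — exceeds ``ξ`` times the first
    component's.  Ties at the cutoff are kept.
    """
    u = np.asarray(u, float)
    indices = np.sort(np.asarray(indices, dtype=int))
    if np.unique(indices).size != indices.size:
        raise ValueError("indices must be distinct")
    s_prime = indices.size if s_prime is None else int(s_prime)
    if s_prime != indices.size:
        raise ValueError("need exactly s_prime indices")
    if xi <= 1:
        raise ValueError("xi must exceed 1")
    u_tilde = u[:, :s_prime]
    u_hat = u_tilde[indices, :]
    u_hat, u_tilde = _gram_schmidt_pair(u_hat, u_tilde)
    if np.linalg.cond(u_hat) > COND_LIMIT:
        raise np.linalg.LinAlgError(
            "restricted basis is numerically singular; choose other indices"
        )
    inv = np.linalg.inv(u_hat)
    row_norms = np.linalg.norm(inv, axis=1)
    rejected = row_norms > xi * row_norms[0]
    inv_filtered = inv.copy()
    inv_filtered[rejected] = 0.0
    return SamplingDesign(
        indices=indices,
        u_tilde=u_tilde,
        u_hat=u_hat,
        inv_filtered=inv_filtered,
        row_norms=row_norms,
        xi=float(xi),
        rejected=rejected,
    )


def reconstruct(D_sparse: np.ndarray, design: SamplingDesign) -> np.ndarray:
    """Reconstruct full-resolution spectra from sparse measurements.

    ``D_sparse`` is ``P × S′``, measured at ``design.indices`` (in
    ascending wavenumber order); the result is ``P × S``.
    """
    D_sparse = np.asarray(D_sparse, float)
    if D_sparse.ndim != 2 or D_sparse.shape[1] != design.s_prime:
        raise ValueError(
            f"expected P × {design.s_prime} sparse data, got {D_sparse.shape}"
        )
    return D_sparse @ design.inv_filtered.T @ design.u_tilde.T


def sparse_error_map(D_full: np.ndarray, D_rec: np.ndarray) -> np.ndarray:
    """Per-point spectral error of the reconstruction,
    ``√(P·Σ_j (D − D_rec)²_pj)/‖D‖_F``."""
    D_full = np.asarray(D_full, float)
    D_rec = np.asarray(D_rec, float)
    if D_full.shape != D_rec.shape:
        raise ValueError("shape mismatch")
    return spectral_error_map(D_full - D_rec, D_full)
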