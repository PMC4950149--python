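"""Factorization into spectra and concentrations of chemical components.

The data model is ``D = C·Sᵀ + E`` with a non-negative ``P × S″`` data
matrix ``D`` (spatial points × spectral channels), non-negative
concentrations ``C`` (``P × k``) and spectra ``S`` (``S″ × k``), solved
by non-negative matrix factorization with multiplicative Frobenius
updates.  Reproducibility despite the random initialization is improved
by a multi-start scheme: ``n`` independent short runs at a coarse
tolerance ``τ_H``, with the best (smallest-error) run continued at a
fine tolerance ``τ_L``.  Absolute concentrations are fixed afterwards by
scaling each component so that the summed concentration at every point
deviates least from unity — a filled sample volume.

Per-point error maps drive the spatial weighting (:mod:`hsunmix.weighted`):

* spectral error  ``E_Sp = √(P·Σ_j E_pj²)/‖D‖_F``
* concentration error  ``E_Cp = (Σ_k C_pk) − 1``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "FSC3Params",
    "FSC3Result",
    "nmf",
    "multi_start_fsc3",
    "spectral_error_map",
    "scale_to_volume_fraction",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class FSC3Params:
    """Factorization parameters.

    ``n`` random starts are run to the coarse tolerance ``tau_H`` and the
    best continued to ``tau_L``; both tolerances are relative RMS changes
    of the factors per iteration (see :func:`nmf`), so the composition
    reaches an overall tolerance of ``tau_H·tau_L`` from the random
    start.  Defaults follow common practice for cell-image unmixing:
    n=10, tau_H=0.1, tau_L=0.01.
    """

    k: int = 2
    n: int = 10
    tau_H: float = 0.1
    tau_L: float = 0.01
    max_iter_nmf: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 < self.tau_H < 1 and 0 < self.tau_L < 1):
            raise ValueError("tolerances must lie in (0, 1)")
        if self.tau_L > self.tau_H:
            raise ValueError("tau_L must not exceed tau_H")


@dataclass
class FSC3Result:
    """Concentrations, spectra and error maps of one factorization."""

    C: np.ndarray  # P × k volume fractions (after scaling)
    S: np.ndarray  # S″ × k component spectra
    E: np.ndarray  # P × S″ residual D − C·Sᵀ
    E_Sp: np.ndarray  # per-point spectral error
    E_Cp: np.ndarray  # per-point concentration error
    weights: np.ndarray  # per-point weights used in the fit
    excluded: np.ndarray  # per-point exclusion mask
    k: int
    final_error: float  # (weighted) Frobenius norm of E
    converged: bool
    scale_factors: np.ndarray | None = None
    history: object | None = None  # model-selection trace, if any


def nmf(
    D: np.ndarray,
    k: int,
    init_C: np.ndarray,
    init_S: np.ndarray,
    tol: float,
    max_iter: int = 5000,
    row_weights: np.ndarray | None = None,
):
    """Weighted NMF by multiplicative Frobenius updates.

    Minimizes ``‖diag(w)·(D − C·Sᵀ)‖_F`` over non-negative factors.  Row
    weighting is implemented exactly by factorizing ``diag(w)·D`` and
    unscaling the concentration rows afterwards, which leaves the
    weighted objective identical.  The stop criterion is the RMS change
    of the concatenated ``(C, S)`` entries per iteration, relative to the
    change in the first iteration, falling below ``tol``.

    Returns ``(C, S, n_iter, trace)`` where ``trace`` holds the relative
    RMS-change and weighted-residual-norm sequences for auditing.
    """
    D = np.asarray(D, float)
    P, Sn = D.shape
    if D.min() < 0:
        raise ValueError("D must be non-negative")
    if not np.any(D > 0):
        raise ValueError("D is all zero")
    if k > min(P, Sn):
        raise ValueError(f"k={k} exceeds min(P, S)={min(P, Sn)}")
    w = None if row_weights is None else np.asarray(row_weights, float)
    if w is not None:
        if w.shape != (P,) or np.any(w <= 0):
            raise ValueError("row_weights must be positive, one per row")
        Dw = D * w[:, None]
        Cw = np.asarray(init_C, float) * w[:, None]
    else:
        Dw = D
        Cw = np.asarray(init_C, float).copy()
    H = np.asarray(init_S, float).T.copy()  # k × S
    if Cw.min() < 0 or H.min() < 0:
        raise ValueError("initial factors must be non-negative")

    first_change = None
    rel_changes: list[float] = []
    resid_norms: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        C_prev, H_prev = Cw, H
        # multiplicative Frobenius updates (Lee–Seung)
        Cw = Cw * (Dw @ H.T) / (Cw @ (H @ H.T) + _EPS)
        H = H * (Cw.T @ Dw) / ((Cw.T @ Cw) @ H + _EPS)
        change = np.sqrt(
            (np.sum((Cw - C_prev) ** 2) + np.sum((H - H_prev) ** 2))
            / (Cw.size + H.size)
        )
        if first_change is None:
            first_change = max(change, _EPS)
        rel = change / first_change
        rel_changes.append(rel)
        resid_norms.append(float(np.linalg.norm(Dw - Cw @ H)))
        if rel < tol:
            break
    C = Cw / w[:, None] if w is not None else Cw
    trace = {
        "rel_change": np.asarray(rel_changes),
        "residual_norm": np.asarray(resid_norms),
        "converged": bool(rel_changes and rel_changes[-1] < tol),
    }
    return C, H.T, n_iter, trace


def _random_init(D: np.ndarray, k: int, rng: np.random.Generator):
    """Uniform(0,1) factors scaled so mean(C·Sᵀ) matches mean(D)."""
    P, Sn = D.shape
    C = rng.uniform(size=(P, k))
    S = rng.uniform(size=(Sn, k))
    scale = np.sqrt(D.mean() / max((C @ S.T).mean(), _EPS))
    return C * scale, S * scale


def spectral_error_map(E: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Per-point spectral error ``E_Sp = √(P·Σ_j E_pj²)/‖D‖_F``.

    Normalized so the RMS over points equals the relative global error
    ``‖E‖_F/‖D‖_F``.
    """
    E = np.asarray(E, float)
    D = np.asarray(D, float)
    if E.shape != D.shape:
        raise ValueError("E and D shapes differ")
    nD = np.linalg.norm(D)
    if nD == 0:
        raise ValueError("‖D‖_F is zero")
    P = D.shape[0]
    return np.sqrt(P * np.sum(E**2, axis=1)) / nD


def scale_to_volume_fraction(C: np.ndarray, S: np.ndarray):
    """Rescale components so summed concentrations best approach unity.

    Finds per-component factors ``a_k ≥ 0`` minimizing
    ``Σ_p (Σ_k a_k·C_pk − 1)²`` by non-negative least squares and returns
    ``(C·diag(a), S·diag(1/a), a)``; the product ``C·Sᵀ`` is unchanged.
    Components assigned ``a_k = 0`` keep their unscaled spectrum and are
    reported through the returned factors.
    """
    C = np.asarray(C, float)
    S = np.asarray(S, float)
    if C.min() < 0 or S.min() < 0:
        raise ValueError("factors must be non-negative")
    if not np.any(C > 0):
        raise ValueError("degenerate C: all rows zero")
    if np.any(~np.any(C > 0, axis=0)):
        raise ValueError("C has an all-zero column")
    a, _ = nnls(C, np.ones(C.shape[0]))
    C_s = C * a
    S_s = S.copy()
    pos = a > 0
    S_s[:, pos] = S[:, pos] / a[pos]
    if not pos.all():
        log.warning("volume-fraction scaling zeroed %d component(s)", int((~pos).sum()))
    return C_s, S_s, a


def _drop_zero_components(C: np.ndarray, S: np.ndarray):
    keep = np.any(S > 0, axis=0) & np.any(C > 0, axis=0)
    if not keep.all():
        log.warning("dropping %d all-zero component(s)", int((~keep).sum()))
    return C[:, keep], S[:, keep]


def multi_start_fsc3(
    D: np.ndarray,
    params: FSC3Params,
    row_weights: np.ndarray | None = None,
) -> FSC3Result:
    """Multi-start factorization: ``n`` coarse runs, best one refined.

    Runs ``n`` independent NMFs from seeded random initializations at
    tolerance ``tau_H``, selects the run with the smallest (weighted)
    residual norm, and continues it at ``tau_L``.  The returned result
    carries the volume-fraction-scaled factors, the recomputable residual
    ``E = D − C·Sᵀ`` and the per-point error maps.  Deterministic given
    ``params.seed``.
    """
    D = np.asarray(D, float)
    children = np.random.SeedSequence(params.seed).spawn(params.n)
    best = None
    for child in children:
        rng = np.random.default_rng(child)
        C0, S0 = _random_init(D, params.k, rng)
        C, S, _, trace = nmf(
            D, params.k, C0, S0, params.tau_H, params.max_iter_nmf, row_weights
        )
        err = trace["residual_norm"][-1]
        if best is None or err < best[0]:
            best = (err, C, S)
    _, C, S = best
    C, S, _, trace = nmf(
        D, params.k, C, S, params.tau_L, params.max_iter_nmf, row_weights
    )
    C, S = _drop_zero_components(C, S)
    if C.shape[1] == 0:
        raise ValueError("factorization collapsed to zero components")
    C, S, a = scale_to_volume_fraction(C, S)
    E = D - C @ S.T
    weights = np.ones(D.shape[0]) if row_weights is None else np.asarray(row_weights, float)
    final_error = float(np.linalg.norm(E * weights[:, None]))
    return FSC3Result(
        C=C,
        S=S,
        E=E,
        E_Sp=spectral_error_map(E, D),
        E_Cp=C.sum(axis=1) - 1.0,
        weights=weights,
        excluded=np.zeros(D.shape[0], dtype=bool),
        k=C.shape[1],
        final_error=final_error,
        converged=bool(trace["converged"]),
        scale_factors=a,
    )
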