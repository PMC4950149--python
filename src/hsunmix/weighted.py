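"""Spatially weighted factorization and unsupervised component count.

A factorization that minimizes only the *global* error effectively
ignores chemical components concentrated in a handful of pixels: their
contribution to the total error is tiny, so their pixels simply end up
with a large local spectral error.  The weighted scheme counteracts this
by giving every spatial point a weight in the objective and iterating

    w_p ← exp(−β·|E_Cp|) · w_p · (E_Sp/Ē_S)^(1−α)

so points whose spectral error sits above the image average gain
influence until the error map is spatially homogeneous.  ``α ∈ [0, 1)``
damps the spectral-error feedback, ``β ∈ [0, 1]`` penalizes deviations
of the summed concentration from a filled volume.  Points whose weight
diverges (e.g. motion artifacts) are excluded once they cross the
threshold ``γ·P^{1/4}`` — a single point of weight ``P^{1/4}``
contributes to ``‖E‖`` as much as ``√P`` unweighted points.

The number of components is chosen unsupervised: ``k`` grows while an
additional component improves the per-point RMS spectral error by more
than ``η`` standard deviations of the spectral-error map,

    ‖E_S^k‖/√P − ‖E_S^{k+1}‖/√P > η·σ(E_S^k),

first with the unweighted factorization, then inside the weighted loop
with add/remove trial steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .fsc3 import FSC3Params, FSC3Result, multi_start_fsc3, spectral_error_map

__all__ = [
    "WeightParams",
    "ModelSelectState",
    "update_weights",
    "exclusion_threshold",
    "weighted_fsc3",
    "component_gain_test",
    "select_components",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the weight iteration.

    Defaults (α=0.3, β=0, γ=10, j=3) are the values that work well for
    cell-image unmixing; α=0 gives the fastest (undamped) weight growth
    and suits strongly localized components.
    """

    alpha: float = 0.3
    beta: float = 0.0
    gamma: float = 10.0
    j_history: int = 3
    max_weight_iters: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.j_history < 1:
            raise ValueError("j_history must be >= 1")


def update_weights(
    w: np.ndarray,
    E_Sp: np.ndarray,
    E_Cp: np.ndarray,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """One multiplicative weight update.

    ``w_next = exp(−β·|E_Cp|) · w · (E_Sp/Ē_S)^{1−α}`` with ``Ē_S`` the
    mean spectral error over the supplied points.  If the fit is perfect
    (all ``E_Sp`` zero) the weights are returned unchanged; otherwise the
    error ratio is floored at a small ε so perfectly fitted single
    points do not collapse their weight to zero.
    """
    w = np.asarray(w, float)
    E_Sp = np.asarray(E_Sp, float)
    E_Cp = np.asarray(E_Cp, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    mean_es = E_Sp.mean()
    if mean_es <= 0:
        return w.copy()
    ratio = np.maximum(E_Sp / mean_es, _EPS)
    return np.exp(-beta * np.abs(E_Cp)) * w * ratio ** (1.0 - alpha)


def exclusion_threshold(gamma: float, P: int) -> float:
    """Weight above which a point is excluded from the fit: ``γ·P^{1/4}``."""
    if gamma <= 0 or P < 1:
        raise ValueError("gamma must be > 0 and P >= 1")
    return gamma * P**0.25


def _project_concentrations(S: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Non-negative projection of spectra rows onto the component basis."""
    return np.array([nnls(S, r)[0] for r in rows]) if len(rows) else np.empty((0, S.shape[1]))


def weighted_fsc3(
    D: np.ndarray,
    params: FSC3Params,
    wparams: WeightParams | None = None,
    w0: np.ndarray | None = None,
) -> FSC3Result:
    """Iterate multi-start factorization and weight updates to a stable
    weight map.

    Weights start at unity (or ``w0``).  Each iteration fits the retained
    points with the current weights, updates the weights from the
    per-point error maps, and excludes points whose weight crosses
    ``γ·P^{1/4}`` (exclusion is monotone — excluded points never
    re-enter, but they receive concentrations afterwards by non-negative
    projection onto the final spectra, so the output maps have no holes).
    The loop stops when the variation norm of the normalized weights,
    ``‖w^{i+1}/mean(w^{i+1}) − w^i/mean(w^i)‖`` over retained points, is
    no longer reduced below any of the last ``j`` values.  The returned
    result is the iterate whose spectral-error map is the most spatially
    homogeneous (smallest coefficient of variation of ``E_Sp``) — the
    quantity the weighting is built to equalize; per-point noise makes
    the variation norm itself drift and unsuitable for picking the best
    iterate.
    """
    wparams = wparams or WeightParams()
    D = np.asarray(D, float)
    P = D.shape[0]
    thresh = exclusion_threshold(wparams.gamma, P)
    w = np.ones(P) if w0 is None else np.asarray(w0, float).copy()
    if w.shape != (P,) or np.any(w <= 0):
        raise ValueError("w0 must be positive, one weight per point")
    retained = w <= thresh
    if not retained.any():
        raise ValueError("all points excluded by the initial weights")
    seeds = np.random.SeedSequence(params.seed).spawn(wparams.max_weight_iters)

    variations: list[float] = []
    homogeneity: list[float] = []
    snapshots: list[tuple] = []
    converged = False
    w_prev = w.copy()
    for i in range(wparams.max_weight_iters):
        it_params = FSC3Params(
            k=params.k,
            n=params.n,
            tau_H=params.tau_H,
            tau_L=params.tau_L,
            max_iter_nmf=params.max_iter_nmf,
            seed=int(seeds[i].generate_state(1)[0] % (2**31)),
        )
        res = multi_start_fsc3(D[retained], it_params, w[retained])
        w_new = w.copy()
        w_new[retained] = update_weights(
            w[retained], res.E_Sp, res.E_Cp, wparams.alpha, wparams.beta
        )
        wn_r = w_new[retained] / w_new[retained].mean()
        wo_r = w[retained] / w[retained].mean()
        v = float(np.linalg.norm(wn_r - wo_r))
        variations.append(v)
        homogeneity.append(float(np.std(res.E_Sp) / max(res.E_Sp.mean(), _EPS)))
        snapshots.append((res, w.copy(), retained.copy(), w_prev.copy()))
        newly_excluded = retained & (w_new > thresh)
        if newly_excluded.any():
            log.info("iteration %d: excluding %d point(s)", i, int(newly_excluded.sum()))
        retained = retained & ~newly_excluded
        if not retained.any():
            raise ValueError("weight iteration excluded every point")
        w_prev = w
        w = w_new
        j = wparams.j_history
        if len(variations) > j and variations[-1] >= min(variations[-1 - j : -1]):
            converged = True
            break

    best_i = int(np.argmin(homogeneity))
    res, w_best, retained_best, w_prev_best = snapshots[best_i]
    return _assemble_full(D, res, w_best, retained_best, converged, w_prev_best)


def _assemble_full(D, res, w, retained, converged, w_prev) -> FSC3Result:
    """Expand a retained-points fit to the full image."""
    P = D.shape[0]
    S = res.S
    C = np.zeros((P, S.shape[1]))
    C[retained] = res.C
    if (~retained).any():
        C[~retained] = _project_concentrations(S, D[~retained])
    E = D - C @ S.T
    out = FSC3Result(
        C=C,
        S=S,
        E=E,
        E_Sp=spectral_error_map(E, D),
        E_Cp=C.sum(axis=1) - 1.0,
        weights=w,
        excluded=~retained,
        k=S.shape[1],
        final_error=float(np.linalg.norm(E[retained] * w[retained, None])),
        converged=converged,
        scale_factors=res.scale_factors,
    )
    out.history = {"w_prev": w_prev}
    return out


def component_gain_test(
    norm_ESk: float,
    norm_ESk1: float,
    sigma_ESk: float,
    eta: float,
    P: int,
) -> bool:
    """Does one more component improve the error enough to keep it?

    True iff the per-point RMS spectral error improves by more than
    ``η`` standard deviations of the spectral-error map:
    ``norm_ESk/√P − norm_ESk1/√P > η·sigma_ESk``.  Passing a negated
    ``sigma_ESk`` turns this into the component-removal acceptance test.
    """
    if norm_ESk < 0 or norm_ESk1 < 0:
        raise ValueError("norms must be non-negative")
    if eta <= 0:
        raise ValueError("eta must be positive")
    return (norm_ESk - norm_ESk1) / np.sqrt(P) > eta * sigma_ESk


@dataclass
class ModelSelectState:
    """Audit trail of the component-count search."""

    eta: float
    history: list = field(default_factory=list)  # (phase, k, ‖E_S‖, σ(E_S))
    k_final: int | None = None

    def record(self, phase: str, k: int, E_Sp: np.ndarray) -> None:
        self.history.append(
            (phase, int(k), float(np.linalg.norm(E_Sp)), float(np.std(E_Sp)))
        )


def _es_stats(res: FSC3Result, retained=None):
    es = res.E_Sp if retained is None else res.E_Sp[retained]
    return float(np.linalg.norm(es)), float(np.std(es)), es.size


def select_components(
    D: np.ndarray,
    params: FSC3Params,
    wparams: WeightParams | None = None,
    eta: float = 0.5,
    k_max: int = 20,
    max_cycles: int = 8,
) -> tuple[int, FSC3Result]:
    """Unsupervised choice of the number of chemical components.

    Phase 1 grows ``k`` from 1 with the unweighted factorization while
    the gain test passes.  Phase 2 runs the weighted iteration at ``k``
    and then trials: fit ``k+1`` with the current weights and accept the
    extra component if the gain test passes; otherwise fit ``k−1`` with
    the previous weights and accept the removal if it costs less than
    ``η`` (negated) standard deviations; otherwise ``k`` is final.  The
    add/remove loop is bounded by ``max_cycles``.

    Returns ``(k_final, result)``; the result's ``history`` field holds a
    :class:`ModelSelectState` audit trail.
    """
    wparams = wparams or WeightParams()
    D = np.asarray(D, float)
    P = D.shape[0]
    state = ModelSelectState(eta=eta)

    def _params(k: int, seed_salt: int) -> FSC3Params:
        return FSC3Params(
            k=k,
            n=params.n,
            tau_H=params.tau_H,
            tau_L=params.tau_L,
            max_iter_nmf=params.max_iter_nmf,
            seed=(params.seed * 1000003 + seed_salt) % (2**31),
        )

    # phase 1: grow k with the unweighted factorization
    k = 1
    res_k = multi_start_fsc3(D, _params(1, 1))
    state.record("grow", 1, res_k.E_Sp)
    while k < min(k_max, min(D.shape) - 1):
        res_up = multi_start_fsc3(D, _params(k + 1, k + 1))
        state.record("grow", k + 1, res_up.E_Sp)
        nk, sk, _ = _es_stats(res_k)
        nk1, _, _ = _es_stats(res_up)
        if component_gain_test(nk, nk1, sk, eta, P):
            k, res_k = k + 1, res_up
        else:
            break

    # phase 2: weighted loop with add/remove trials
    wres = weighted_fsc3(D, _params(k, 100), wparams)
    state.record("weighted", k, wres.E_Sp)
    for cycle in range(max_cycles):
        retained = ~wres.excluded
        w = wres.weights
        # error stats recomputed on the retained submatrix so that the
        # normalization of E_Sp matches the trial fits below
        es_k = spectral_error_map(wres.E[retained], D[retained])
        nk, sk, n_ret = float(np.linalg.norm(es_k)), float(np.std(es_k)), es_k.size
        # trial: one more component, current weights
        res_up = multi_start_fsc3(D[retained], _params(k + 1, 200 + cycle), w[retained])
        nk1 = float(np.linalg.norm(res_up.E_Sp))
        state.record("try_add", k + 1, res_up.E_Sp)
        if component_gain_test(nk, nk1, sk, eta, n_ret):
            k += 1
            wres = weighted_fsc3(D, _params(k, 100 + cycle + 1), wparams, w0=w)
            state.record("weighted", k, wres.E_Sp)
            continue
        if k > 1:
            # trial: one fewer component, previous weights
            w_prev = (wres.history or {}).get("w_prev", w)
            res_dn = multi_start_fsc3(
                D[retained], _params(k - 1, 300 + cycle), w_prev[retained]
            )
            nkm1 = float(np.linalg.norm(res_dn.E_Sp))
            state.record("try_remove", k - 1, res_dn.E_Sp)
            if component_gain_test(nk, nkm1, -sk, eta, n_ret):
                k -= 1
                wres = weighted_fsc3(D, _params(k, 100 + cycle + 1), wparams, w0=w_prev)
                state.record("weighted", k, wres.E_Sp)
                continue
        break
    else:
        log.warning("component search hit the cycle bound; returning k=%d", k)
    state.k_final = k
    wres.history = state
    return k, wres
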