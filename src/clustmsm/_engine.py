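"""Vectorised numerical core: intensity jumps, product integrals, influence.

Everything here operates on dense arrays laid out on the pooled jump-time
grid, with an optional leading batch axis so that cluster-bootstrap
resamples are processed in one shot (the batch axis carries the resample
multiplicities through the weighted aggregation).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .processes import ClusterProcesses

__all__ = [
    "intensity_jumps",
    "product_integral_path",
    "influence_path",
    "occupation_curve",
    "transition_curve",
]


def _trans_indices(space) -> Tuple[np.ndarray, np.ndarray]:
    src = np.array([h - 1 for h, _ in space.transitions], dtype=np.intp)
    dst = np.array([j - 1 for _, j in space.transitions], dtype=np.intp)
    return src, dst


def intensity_jumps(wdN: np.ndarray, wY: np.ndarray, space) -> np.ndarray:
    """Nelson-Aalen-type jumps ``dA_hj(u) = wdN_hj(u) / wY_h(u)``.

    Times with a zero (weighted) at-risk sum contribute no jump
    (the 0/0 convention), matching the support of the defining integral.
    """
    src, _ = _trans_indices(space)
    den = wY[..., src]
    with np.errstate(divide="ignore", invalid="ignore"):
        dA = np.where(den > 0, wdN / np.where(den > 0, den, 1.0), 0.0)
    return dA


def _delta_matrices(dA: np.ndarray, space) -> np.ndarray:
    """Jump matrices ``dA(u)`` with diagonal ``-(row sums)``."""
    src, dst = _trans_indices(space)
    k = space.k
    lead = dA.shape[:-1]
    delta = np.zeros(lead + (k, k))
    for c in range(dA.shape[-1]):
        delta[..., src[c], dst[c]] += dA[..., c]
    rows = delta.sum(axis=-1)
    idx = np.arange(k)
    delta[..., idx, idx] -= rows
    return delta


def product_integral_path(dA: np.ndarray, space) -> np.ndarray:
    """Cumulative product integral ``P(r) = prod_{u<=r} (I + dA(u))``.

    ``dA`` has shape ``(..., T, C)``; the result has shape
    ``(..., T, k, k)`` with entry ``r`` the product over the first ``r+1``
    grid times, computed left-to-right in a single sweep.  Raises when a
    factor ``I + dA(u)`` has a negative entry (a jump exceeding one).
    """
    k = space.k
    delta = _delta_matrices(dA, space)
    T = delta.shape[-3]
    idx = np.arange(k)
    diag = 1.0 + delta[..., idx, idx]
    if T and diag.min() < -1e-12:
        raise ValueError("invalid jump: a row of I + dA(u) has a negative entry")
    lead = delta.shape[:-3]
    out = np.empty(lead + (T, k, k))
    P = np.broadcast_to(np.eye(k), lead + (k, k)).copy()
    eye = np.eye(k)
    for r in range(T):
        P = P @ (eye + delta[..., r, :, :])
        out[..., r, :, :] = P
    return out


def influence_path(
    dN: np.ndarray,
    Y: np.ndarray,
    w: np.ndarray,
    dA: np.ndarray,
    Ppath: np.ndarray,
    space,
    entries=None,
) -> np.ndarray:
    """Estimated per-cluster influence functions of the transition matrix.

    Implements the ratio linearisation of the weighted Nelson-Aalen
    increments propagated through the Duhamel expansion of the product
    integral: with per-cluster intensity residuals

    ``d_alpha_i,hj(u) = w_i {dN_i,hj(u) - Y_i,h(u) dA_hj(u)} / n^{-1} sum_l w_l Y_l,h(u)``

    the influence of cluster ``i`` on ``P(s, t)`` is

    ``gamma_i(s, t) = sum_{u in (s, t]} P(s, u-) dD_i(u) P(u, t)``

    where ``dD_i`` is the residual matrix with diagonal ``-(row sums)``.
    The sum over ``u`` is accumulated forward in one sweep via
    ``G(t_r) = G(t_{r-1})(I + dA(t_r)) + P(s, t_{r-1}) dD_i(t_r)``.

    Parameters are the per-cluster arrays on the (already sliced) grid,
    the aggregated jumps ``dA`` and the product-integral path ``Ppath``
    over the same grid.  ``entries`` selects which matrix entries
    ``(h-1, j-1)`` to record along the path (all ``k*k`` by default).
    Returns ``gamma`` of shape ``(n, T, k, k)`` (or ``(n, T, E)`` when
    ``entries`` is given); the influence functions are centred:
    ``sum_i gamma_i(t) = 0``.
    """
    src, dst = _trans_indices(space)
    k = space.k
    n, T, C = dN.shape

    wY = np.tensordot(w, Y, axes=(0, 0))  # (T, k)
    den = wY[:, src] / n
    with np.errstate(divide="ignore"):
        invden = np.where(den > 0, 1.0 / np.where(den > 0, den, 1.0), 0.0)
    # residual increments, time-major and contiguous for the sweep
    R = np.ascontiguousarray(
        (w[:, None, None] * (dN - Y[:, :, src] * dA[None, :, :]) * invden[None, :, :])
        .transpose(1, 0, 2)
    )  # (T, n, C)

    # residual matrices with diagonal -(row sums), time-major
    dD = np.zeros((T, n, k, k))
    for c in range(C):
        dD[:, :, src[c], dst[c]] += R[:, :, c]
    idx = np.arange(k)
    dD[:, :, idx, idx] -= dD.sum(axis=-1)

    delta = _delta_matrices(dA, space)
    eye = np.eye(k)
    factors = eye + delta  # (T, k, k)
    sel = entries
    out = (
        np.empty((n, T, k, k)) if sel is None else np.empty((n, T, len(sel)))
    )
    G = np.zeros((n, k, k))
    Pprev = eye
    for r in range(T):
        G = G @ factors[r] + Pprev @ dD[r]
        if sel is None:
            out[:, r] = G
        else:
            for e, (hdx, jdx) in enumerate(sel):
                out[:, r, e] = G[:, hdx, jdx]
        Pprev = Ppath[r]
    return out


def bootstrap_counts(
    rng: np.random.Generator,
    procs: ClusterProcesses,
    n_draws: int,
    require_observed_at_zero: bool = False,
    max_rounds: int = 10,
) -> np.ndarray:
    """Cluster-resampling multiplicity matrix ``(n_draws, n)``.

    Each row is a multinomial draw of ``n`` clusters with replacement.
    When ``require_observed_at_zero`` is set (occupation targets under
    left truncation), degenerate resamples with nobody under observation
    at time zero are redrawn, up to ``max_rounds`` passes.
    """
    n = procs.n
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=int(n_draws))
    if require_observed_at_zero:
        u = procs.Y0p.sum(axis=1) / procs.M
        for _ in range(max_rounds):
            bad = counts @ u <= 0
            if not bad.any():
                break
            counts[bad] = rng.multinomial(n, np.full(n, 1.0 / n), size=int(bad.sum()))
        else:
            raise RuntimeError(
                "cluster bootstrap kept producing resamples with no subjects "
                "under observation at time zero"
            )
    return counts


def independence_variance(
    dNagg: np.ndarray,
    Yagg: np.ndarray,
    dA: np.ndarray,
    space,
    init: np.ndarray,
    jdx: int,
) -> np.ndarray:
    """Classical i.i.d. Aalen-Johansen (Greenwood-type) variance path.

    Treats subjects as independent: propagates the covariance of the
    influence row ``g(t) = init' gamma(t)`` through the product-integral
    recursion, accumulating at each jump the multinomial innovation
    variance of the Nelson-Aalen increments and dropping the
    between-time cross terms (martingale orthogonality).  In the
    two-state survival case this reduces exactly to Greenwood's formula.

    ``init`` is the row weighting over starting states (a unit vector
    for a single transition target, the initial-state weights for an
    occupation target); ``jdx`` the zero-based destination state.
    Returns the variance of the estimator itself on the grid.
    """
    src, dst = _trans_indices(space)
    k = space.k
    T, C = dA.shape
    same_h = (src[:, None] == src[None, :])
    delta = _delta_matrices(dA, space)
    eye = np.eye(k)
    S = np.zeros((k, k))
    prow = np.asarray(init, dtype=float).copy()
    var = np.empty(T)
    dN = dNagg.astype(float)
    Y = Yagg.astype(float)
    for r in range(T):
        den = Y[r, src]
        ok = den > 0
        iden = np.where(ok, 1.0 / np.where(ok, den, 1.0), 0.0)
        dNr, dAr = dN[r], dA[r]
        m = (
            np.diag(dNr)
            - same_h * (dAr[:, None] * dNr[None, :] + dAr[None, :] * dNr[:, None])
            + same_h * (dAr[:, None] * dAr[None, :]) * den[:, None]
        ) * (iden[:, None] * iden[None, :])
        V = np.zeros((C, k))
        V[np.arange(C), dst] += prow[src]
        V[np.arange(C), src] -= prow[src]
        F = eye + delta[r]
        S = F.T @ S @ F + V.T @ m @ V
        var[r] = S[jdx, jdx]
        prow = prow @ F
    return var


def _slice_grid(procs: ClusterProcesses, s: float, t_max: Optional[float] = None):
    """Indices of grid times in ``(s, t_max]``."""
    lo = np.searchsorted(procs.times, s, side="right")
    hi = len(procs.times) if t_max is None else np.searchsorted(procs.times, t_max, side="right")
    return slice(lo, hi)


def transition_curve(
    procs: ClusterProcesses,
    s: float = 0.0,
    coef: Optional[np.ndarray] = None,
    t_max: Optional[float] = None,
):
    """Transition probability path ``P(s, t)`` on the jump grid after ``s``.

    Returns ``(times, dA, Ppath)`` where ``times`` are the grid times in
    ``(s, t_max]``, ``dA`` the aggregated intensity jumps there and
    ``Ppath`` the product-integral path (leading batch axes follow
    ``coef``).
    """
    sl = _slice_grid(procs, s, t_max)
    wdN, wY = procs.aggregate(coef)
    dA = intensity_jumps(wdN[..., sl, :], wY[..., sl, :], procs.space)
    Ppath = product_integral_path(dA, procs.space)
    return procs.times[sl], dA, Ppath


def occupation_weights(procs: ClusterProcesses, coef: Optional[np.ndarray] = None):
    """Initial-state weights ``c_h`` and ``pi_hat`` of the occupation estimator.

    ACM: ``c_h = sum_i Y_i.,h(0+) / (pi_hat sum_i M_i)``;
    TCM: ``c_h = n^{-1} sum_i M_i^{-1} Y_i.,h(0+) / pi_hat``; with
    ``pi_hat = n^{-1} sum_i M_i^{-1} sum_h Y_i.,h(0+)`` the estimated
    probability of being under observation at time zero.
    """
    n = procs.n
    Y0p = procs.Y0p.astype(float)
    M = procs.M.astype(float)
    u = Y0p.sum(axis=1) / M
    ones = np.ones(n) if coef is None else np.asarray(coef)
    pi = np.tensordot(ones, u, axes=([-1], [0])) / n
    if np.any(pi <= 0):
        raise ValueError("no subjects under observation at time zero")
    if procs.population == "acm" or procs.constant_size:
        num = np.tensordot(ones, Y0p, axes=([-1], [0]))
        tot = np.tensordot(ones, M, axes=([-1], [0]))
        c = num / (pi * tot)[..., None]
    else:
        num = np.tensordot(ones, Y0p / M[:, None], axes=([-1], [0]))
        c = num / (n * pi)[..., None]
    # absorbing states carry no initial mass in the estimator
    for a in procs.space.absorbing:
        c[..., a - 1] = 0.0
    return c, pi


def occupation_curve(
    procs: ClusterProcesses,
    coef: Optional[np.ndarray] = None,
    t_max: Optional[float] = None,
):
    """State occupation probability path ``P_j(t)`` on the jump grid.

    ``P_j(t) = sum_{h transient} c_h P_hj(0, t)`` with the time-zero
    weights of :func:`occupation_weights`.  Returns
    ``(times, occ, pi, c, dA, Ppath)``.
    """
    times, dA, Ppath = transition_curve(procs, 0.0, coef, t_max)
    c, pi = occupation_weights(procs, coef)
    occ = np.einsum("...h,...thj->...tj", c, Ppath)
    return times, occ, pi, c, dA, Ppath


def step_eval(times: np.ndarray, values: np.ndarray, at, fill_start) -> np.ndarray:
    """Right-continuous step-function evaluation with left fill value.

    ``values`` has time on its first axis; ``fill_start`` is returned for
    query points before the first jump.
    """
    at = np.atleast_1d(np.asarray(at, dtype=float))
    idx = np.searchsorted(times, at, side="right") - 1
    out = np.empty((len(at),) + values.shape[1:])
    for q, i in enumerate(idx):
        out[q] = values[i] if i >= 0 else fill_start
    return out
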