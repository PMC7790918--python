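"""Cluster-robust inference: influence functions, bootstrap, bands.

Two asymptotically equivalent inference routes are provided.  The fast
route uses estimated per-cluster influence functions: their empirical
second moments give pointwise variances, and perturbing their sum with
i.i.d. standard normal multipliers simulates the limiting Gaussian
process (wild/multiplier bootstrap).  The reference route is the
nonparametric cluster bootstrap: resample whole clusters with
replacement and recompute the estimator, which is valid under arbitrary
within-cluster dependence and informative cluster size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _engine
from .estimators import StateOccupation, TransitionProbability

__all__ = [
    "InfluenceSet",
    "BandResult",
    "influence_transition",
    "influence_occupation",
    "working_independence_influence",
    "working_independence_variance",
    "multiplier_draws",
    "cluster_bootstrap",
    "bootstrap_curves",
    "pointwise_ci",
    "confidence_band",
]


# ---------------------------------------------------------------------------
# transforms g with derivative and inverse, used for CIs and bands
def _loglog(p):
    return np.log(-np.log(p))


TRANSFORMS = {
    "loglog": (_loglog, lambda p: 1.0 / (p * np.log(p)), lambda y: np.exp(-np.exp(y))),
    "log": (np.log, lambda p: 1.0 / p, np.exp),
    "identity": (lambda p: p, lambda p: np.ones_like(p), lambda y: y),
}


@dataclass
class InfluenceSet:
    """Per-cluster influence functions of one scalar-valued target path.

    ``gamma`` has shape ``(n, T)`` on the grid ``times``; the functions
    are centred (``sum_i gamma_i(t) = 0``) and the pointwise variance of
    the estimator is ``n^{-2} sum_i gamma_i(t)^2``.
    """

    kind: str
    population: str
    target: tuple
    times: np.ndarray
    gamma: np.ndarray

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    def variance(self) -> np.ndarray:
        """Estimated asymptotic variance of ``sqrt(n) (est - truth)``."""
        return (self.gamma**2).sum(axis=0) / self.n

    def se(self) -> np.ndarray:
        """Pointwise standard error of the estimator itself."""
        return np.sqrt((self.gamma**2).sum(axis=0)) / self.n


def influence_transition(
    estimator: TransitionProbability, h: int, j: int
) -> InfluenceSet:
    """Influence functions of ``P_hj(s, .)`` from a fitted estimator."""
    gamma = estimator.influence_path(entries=[(int(h) - 1, int(j) - 1)])[:, :, 0]
    return InfluenceSet(
        kind="transition",
        population=estimator.population,
        target=(estimator.origin, int(h), int(j)),
        times=estimator.times_,
        gamma=gamma,
    )


def influence_occupation(estimator: StateOccupation, j: int) -> InfluenceSet:
    """Influence functions of the occupation probability ``P_j(.)``.

    Delta-method combination of (a) the transition-matrix influence
    functions for each ``P_hj(0, .)``, (b) the residuals of the initial
    at-risk counts ``Y_i.,h(0+)``, and (c) the residuals of ``pi_hat``
    and (ACM) of the total size ``sum_i M_i``.  In the no-truncation,
    single-initial-state case this reduces exactly to the transition
    influence functions.
    """
    jdx = int(j) - 1
    c = estimator.initial_weights_
    space = estimator.processes_.space
    entries = [(h - 1, jdx) for h in space.transient if c[h - 1] != 0.0]
    gam = estimator.influence_path(entries=entries)
    gammas = {hdx: gam[:, :, e] for e, (hdx, _) in enumerate(entries)}
    psi = _occupation_psi(
        estimator.processes_, gammas, c, estimator.prob_path_, jdx
    )
    return InfluenceSet(
        kind="occupation",
        population=estimator.processes_.population,
        target=(int(j),),
        times=estimator.times_,
        gamma=psi,
    )


def _occupation_psi(procs, gammas, c, P, jdx) -> np.ndarray:
    """Delta-method influence functions of ``P_j`` from process arrays.

    ``gammas`` maps the zero-based index of each contributing initial
    state ``h`` to the ``(n, T)`` influence path of ``P_hj(0, .)``.
    """
    space = procs.space
    Y0p = procs.Y0p.astype(float)
    M = procs.M.astype(float)
    u = Y0p.sum(axis=1) / M
    pi = u.mean()

    first = next(iter(gammas.values()))
    psi = np.zeros(first.shape)
    for h in space.transient:
        hdx = h - 1
        ch = c[hdx]
        if ch == 0.0:
            continue
        psi += ch * gammas[hdx]
        if procs.population == "acm" or procs.constant_size:
            a_h = Y0p[:, hdx].mean()
            m_bar = M.mean()
            if_c = ch * (
                (Y0p[:, hdx] - a_h) / a_h - (u - pi) / pi - (M - m_bar) / m_bar
            )
        else:
            b_h = (Y0p[:, hdx] / M).mean()
            if_c = ch * ((Y0p[:, hdx] / M - b_h) / b_h - (u - pi) / pi)
        psi += if_c[:, None] * P[None, :, hdx, jdx]
    return psi


def working_independence_influence(estimator, target) -> InfluenceSet:
    """Influence functions computed as if every subject were independent.

    Rebuilds the processes with each subject as its own cluster of size
    one and reruns the same influence machinery; the resulting variance
    is the classical i.i.d. Aalen-Johansen (Greenwood-type) variance that
    ignores the within-cluster dependence.  This is the "naive"
    comparator, not a recommended analysis.
    """
    from .processes import build_cluster_processes

    df = estimator.episodes_
    space = estimator.processes_.space
    if isinstance(estimator, StateOccupation):
        first_entry = df.groupby(["cluster", "id"])["entry"].transform("min")
        truncated = bool((first_entry > 0).any())
        sub = df[first_entry == 0.0] if truncated else None
        procs = build_cluster_processes(
            df, space, "acm", t_max=estimator.t_max,
            subject_as_cluster=True, counting_subjects=sub,
        )
        est = StateOccupation(space, "acm", validate=False)
        est.processes_ = procs
        times, occ, pi, c, dA, Ppath = _engine.occupation_curve(procs)
        est.times_, est.occupation_, est.pi_ = times, occ, float(pi)
        est.initial_weights_, est.jumps_, est.prob_path_ = c, dA, Ppath
        est._influence_cache = {}
        return influence_occupation(est, target)
    procs = build_cluster_processes(
        df, space, "acm", t_max=estimator.t_max, subject_as_cluster=True
    )
    est = TransitionProbability(
        space, "acm", origin=estimator.origin, validate=False
    )
    est.processes_ = procs
    times, dA, Ppath = _engine.transition_curve(procs, estimator.origin)
    est.times_, est.jumps_, est.prob_ = times, dA, Ppath
    est.n_clusters_ = procs.n
    est._influence_cache = {}
    h, j = target
    return influence_transition(est, h, j)


def working_independence_variance(estimator, target) -> np.ndarray:
    """Naive (Greenwood-type) variance path treating subjects as independent.

    Uses the unweighted pooled counting and at-risk processes in the
    classical i.i.d. Aalen-Johansen covariance recursion; see
    :func:`clustmsm._engine.independence_variance`.  The result does not
    depend on the target population (the naive analysis ignores both the
    clustering and the weights).
    """
    procs = estimator.processes_
    space = procs.space
    origin = 0.0 if isinstance(estimator, StateOccupation) else estimator.origin
    sl = _engine._slice_grid(procs, origin)
    dNagg = procs.dN[:, sl].sum(axis=0)
    Yagg = procs.Y[:, sl].sum(axis=0)
    dA = _engine.intensity_jumps(dNagg.astype(float), Yagg.astype(float), space)
    if isinstance(estimator, StateOccupation):
        init = estimator.initial_weights_
        jdx = int(target) - 1
    else:
        h, j = target
        init = np.zeros(space.k)
        init[int(h) - 1] = 1.0
        jdx = int(j) - 1
    return _engine.independence_variance(dNagg, Yagg, dA, space, init, jdx)


def multiplier_draws(
    influence: InfluenceSet,
    n_draws: int,
    seed=None,
    weight: Optional[np.ndarray] = None,
    slope: Optional[np.ndarray] = None,
    domain: Optional[np.ndarray] = None,
    return_processes: bool = True,
):
    """Wild multiplier realisations of the limiting process.

    Each draw is ``B(t) = n^{-1/2} sum_i gamma_i(t) xi_i`` with i.i.d.
    standard normal ``xi``.  When ``weight`` (``q``) and ``slope``
    (``g'(P)``) are supplied, the sup-statistics
    ``sup_t |q(t) g'(P(t)) B(t)|`` over the boolean ``domain`` are also
    returned.  Returns a dict with keys ``processes`` and/or ``sups``.
    """
    if influence.n < 2:
        raise ValueError("multiplier draws require at least two clusters")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((int(n_draws), influence.n))
    B = xi @ influence.gamma / math.sqrt(influence.n)
    out = {}
    if return_processes:
        out["processes"] = B
    if weight is not None or slope is not None:
        q = np.ones(B.shape[1]) if weight is None else weight
        s = np.ones(B.shape[1]) if slope is None else slope
        Z = np.abs(q * s * B)
        if domain is not None:
            Z = Z[:, domain]
        out["sups"] = Z.max(axis=1) if Z.shape[1] else np.zeros(B.shape[0])
    return out


def cluster_bootstrap(
    episodes: pd.DataFrame,
    B: int,
    statistic: Callable[[pd.DataFrame], object],
    seed=None,
    max_failures: Optional[int] = None,
):
    """Nonparametric cluster bootstrap of an arbitrary table statistic.

    Samples ``n`` clusters with replacement (resampled copies relabelled
    as distinct clusters), rebuilds the episode table and applies
    ``statistic``.  Returns ``(values, original)`` where ``values`` has
    length ``B``.  A failing resample is redrawn, up to ``10 * B``
    redraws in total.
    """
    ids = pd.unique(episodes["cluster"])
    n = len(ids)
    row_idx = {c: np.flatnonzero(episodes["cluster"].to_numpy() == c) for c in ids}
    rng = np.random.default_rng(seed)
    cap = 10 * B if max_failures is None else max_failures
    original = statistic(episodes)
    values = []
    failures = 0
    while len(values) < B:
        pick = rng.integers(0, n, n)
        rows = np.concatenate([row_idx[ids[p]] for p in pick])
        tab = episodes.iloc[rows].copy()
        tab["cluster"] = np.repeat(
            np.arange(n), [len(row_idx[ids[p]]) for p in pick]
        )
        sizes = episodes.attrs.get("cluster_size")
        if sizes is not None:
            tab.attrs["cluster_size"] = {
                i: sizes[ids[p]] for i, p in enumerate(pick)
            }
        try:
            values.append(statistic(tab))
        except Exception:
            failures += 1
            if failures > cap:
                raise RuntimeError(
                    f"cluster bootstrap exceeded {cap} failed resamples"
                )
    return values, original


def bootstrap_curves(estimator, target, n_draws: int, seed=None) -> np.ndarray:
    """Cluster-bootstrap realisations of one estimated probability path.

    Resamples clusters with replacement at the level of the aggregated
    cluster processes (equivalent to resampling the episode table) and
    recomputes the full estimator, vectorised over resamples.  Returns an
    ``(n_draws, T)`` array on ``estimator.times_``.
    """
    procs = estimator.processes_
    rng = np.random.default_rng(seed)
    counts = _engine.bootstrap_counts(
        rng, procs, n_draws,
        require_observed_at_zero=isinstance(estimator, StateOccupation),
    )
    if isinstance(estimator, StateOccupation):
        j = int(target)
        _, occ, _, _, _, _ = _engine.occupation_curve(procs, coef=counts)
        return occ[:, :, j - 1]
    h, j = target
    _, _, Ppath = _engine.transition_curve(procs, estimator.origin, coef=counts)
    return Ppath[:, :, int(h) - 1, int(j) - 1]


def pointwise_ci(p, var, transform="loglog", alpha=0.05):
    """Transformed Wald interval ``g^{-1}(g(p) -+ z sqrt(var) g'(p))``.

    Degenerate estimates (``p`` at 0 or 1) yield the point interval.
    Vectorised over ``p`` and ``var``; returns ``(lower, upper)``.
    """
    from scipy.stats import norm

    g, dg, ginv = TRANSFORMS[transform]
    p = np.asarray(p, dtype=float)
    var = np.asarray(var, dtype=float)
    z = norm.ppf(1 - alpha / 2)
    interior = (p > 0) & (p < 1) if transform != "identity" else np.ones_like(p, bool)
    ps = np.where(interior, p, 0.5)
    half = z * np.sqrt(var) * np.abs(dg(ps))
    lo = ginv(g(ps) - half)
    hi = ginv(g(ps) + half)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    lo = np.where(interior, lo, p)
    hi = np.where(interior, hi, p)
    if transform == "identity":
        lo, hi = np.clip(lo, 0, 1), np.clip(hi, 0, 1)
    return lo, hi


@dataclass
class BandResult:
    """A simultaneous confidence band on a restricted time interval."""

    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    c_alpha: float
    q: np.ndarray
    interval: Tuple[float, float]
    alpha: float
    method: str
    transform: str
    n_draws: int
    seed: object
    excluded: np.ndarray  # grid times flagged out (estimate at 0/1)

    def contains(self, truth: np.ndarray) -> bool:
        """Whether a true curve (on ``times``) lies inside the band."""
        return bool(np.all((truth >= self.lower) & (truth <= self.upper)))


def _observed_transition_times(procs, target, kind) -> np.ndarray:
    """Pooled observed transition times feeding the band-domain rule."""
    space = procs.space
    if kind == "occupation":
        cols = [c for c, (h, j) in enumerate(space.transitions) if j == int(target)]
    else:
        cols = [space.transitions.index((int(target[0]), int(target[1])))]
    counts = procs.dN[:, :, cols].sum(axis=(0, 2))
    return np.repeat(procs.times, counts)


def confidence_band(
    estimator,
    target,
    interval: Optional[Tuple[float, float]] = None,
    restrict: Tuple[float, float] = (0.1, 0.9),
    alpha: float = 0.05,
    method: str = "multiplier",
    n_draws: int = 1000,
    seed=None,
    transform: str = "loglog",
    influence: Optional[InfluenceSet] = None,
) -> BandResult:
    """1 - alpha simultaneous confidence band for a probability path.

    The critical value ``c_alpha`` is the empirical ``ceil((1-alpha) D)``
    order statistic of ``sup_t |q(t) g'(P(t)) Z(t)|`` over the interval,
    with ``Z`` either multiplier realisations of the limit process or
    ``sqrt(n) (P* - P)`` over cluster-bootstrap resamples; the band is
    ``g^{-1}(g(P(t)) +- c_alpha / (sqrt(n) q(t)))`` with the default
    weight ``q(t) = (1 + var_hat(t))^{-1}``.  Unless ``interval`` is
    given, the domain is clipped to the ``restrict`` percentiles of the
    observed transition times feeding the target (bands are unstable at
    the edges of the observation window).
    """
    if isinstance(estimator, StateOccupation):
        kind, tgt = "occupation", int(target)
        curve = estimator.curve(tgt)
    else:
        kind, tgt = "transition", (int(target[0]), int(target[1]))
        curve = estimator.curve(*tgt)
    times = estimator.times_
    procs = estimator.processes_

    if influence is None:
        influence = (
            influence_occupation(estimator, tgt)
            if kind == "occupation"
            else influence_transition(estimator, *tgt)
        )
    # the sqrt(n) scaling must match the units of the influence functions
    # (subject-level for the naive working-independence band)
    n = influence.n if method == "multiplier" else procs.n
    q = 1.0 / (1.0 + influence.variance())

    if interval is None:
        obs = _observed_transition_times(procs, target, kind)
        if len(obs) == 0:
            raise ValueError("no observed transitions; cannot restrict the band domain")
        t1, t2 = np.quantile(obs, restrict[0]), np.quantile(obs, restrict[1])
    else:
        t1, t2 = interval

    domain = (times >= t1) & (times <= t2)
    interior = (curve > 0) & (curve < 1)
    excluded = times[domain & ~interior]
    mask = domain & interior
    if not mask.any():
        raise ValueError("empty band domain")

    if n_draws < 100:
        warnings.warn("fewer than 100 draws; the band critical value is unstable")

    g, dg, ginv = TRANSFORMS[transform]
    slope = np.zeros_like(curve)
    slope[interior] = np.abs(dg(curve[interior]))

    if method == "multiplier":
        sups = multiplier_draws(
            influence, n_draws, seed=seed, weight=q, slope=slope,
            domain=mask, return_processes=False,
        )["sups"]
    elif method in ("bootstrap", "cluster_bootstrap"):
        curves = bootstrap_curves(estimator, target, n_draws, seed=seed)
        Z = np.abs(q * slope * (curves - curve)) * math.sqrt(n)
        sups = Z[:, mask].max(axis=1)
    else:
        raise ValueError(f"unknown band method {method!r}")

    order = int(np.ceil((1 - alpha) * len(sups))) - 1
    c_alpha = float(np.sort(sups)[order])

    half = c_alpha / (math.sqrt(n) * q[mask])
    gp = g(curve[mask])
    lo = ginv(gp - half)
    hi = ginv(gp + half)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return BandResult(
        times=times[mask],
        estimate=curve[mask],
        lower=np.clip(lo, 0.0, 1.0),
        upper=np.clip(hi, 0.0, 1.0),
        c_alpha=c_alpha,
        q=q[mask],
        interval=(float(t1), float(t2)),
        alpha=alpha,
        method=method,
        transform=transform,
        n_draws=n_draws,
        seed=seed,
        excluded=excluded,
    )
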