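"""Two-sample Kolmogorov-Smirnov-type tests for clustered multistate data.

The null hypothesis is equality of a population-averaged probability path
between two groups observed within the same clusters (e.g. the arms of a
multicenter trial): a transition probability ``P_hj(s, .)`` or a state
occupation probability ``P_j(.)``, over the ACM or TCM population.  The
statistic is ``K = sup_t |W(t) D(t)|`` with ``D`` the difference of the
group-specific estimates and ``W`` a weight that vanishes wherever either
group has an empty risk path for the target.  The null distribution of
``sqrt(n) K`` is approximated either by multiplier realisations of the
difference of the group influence processes or by the nonparametric
cluster bootstrap of the centred difference, with the weight frozen at
its data value across resamples.

An informative-cluster-size diagnostic compares the ACM and TCM
occupation estimates within one sample: the two targets coincide when
cluster size is noninformative, so a large weighted sup-difference is
evidence of informativeness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine
from .episodes import landmark_transform, validate_episodes
from .inference import _occupation_psi
from .processes import ClusterProcesses, build_cluster_processes
from .state_space import StateSpace, reachable_transient_states

__all__ = ["KSTestResult", "ks_weight", "ks_test", "ics_test"]


@dataclass
class KSTestResult:
    """Result of a Kolmogorov-Smirnov-type two-sample or ICS test."""

    statistic: float          # K = sup_t |W(t) D(t)|
    scaled_statistic: float   # sqrt(n) K, compared against the null draws
    p_value: float
    target: tuple
    population: str
    weight_type: str
    method: str
    n_draws: int
    n_clusters: int
    seed: object
    times: np.ndarray
    weight: np.ndarray
    difference: np.ndarray


def _weight_states(space: StateSpace, target) -> list:
    """States whose risk paths gate the comparison (the set L)."""
    if target[0] == "occupation":
        j = int(target[1])
        L: set = set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for h in space.transient:
                L |= reachable_transient_states(space, h, j)
    else:
        _, _, h, j = target
        L = reachable_transient_states(space, int(h), int(j))
    return sorted(L)


def ks_weight(
    procs1: ClusterProcesses,
    procs2: ClusterProcesses,
    target,
    weight_type: str = "product",
) -> np.ndarray:
    """Weight path ``W(t)`` on the grid shared by the two process sets.

    With mean at-risk paths ``Ybar_p,l(t)`` (population-weighted, per
    group ``p``), the ``indicator`` weight is
    ``I[prod_l Ybar_1,l Ybar_2,l > 0]`` and the ``product`` weight is
    ``prod_l Ybar_1,l Ybar_2,l / sum_l (Ybar_1,l + Ybar_2,l)``, the
    product running over the transient states that can be visited during
    the target transition.  Both vanish wherever either group has an
    empty risk path.
    """
    space = procs1.space
    idx = [l - 1 for l in _weight_states(space, target)]
    if not idx:
        return np.zeros(len(procs1.times))
    Y1 = procs1.aggregate()[1] / procs1.n
    Y2 = procs2.aggregate()[1] / procs2.n
    prod = np.prod(Y1[:, idx], axis=1) * np.prod(Y2[:, idx], axis=1)
    if weight_type == "indicator":
        return (prod > 0).astype(float)
    if weight_type == "product":
        den = (Y1[:, idx] + Y2[:, idx]).sum(axis=1)
        return np.where(den > 0, prod / np.where(den > 0, den, 1.0), 0.0)
    raise ValueError("weight_type must be 'product' or 'indicator'")


def _occupation_pieces(df, space, population, grid, roster):
    first_entry = df.groupby(["cluster", "id"])["entry"].transform("min")
    truncated = bool((first_entry > 0).any())
    sub = df[first_entry == 0.0] if truncated else None
    procs = build_cluster_processes(
        df, space, population, grid=grid, cluster_index=roster,
        counting_subjects=sub,
    )
    times, occ, pi, c, dA, Ppath = _engine.occupation_curve(procs)
    return procs, times, occ, c, dA, Ppath


def _transition_pieces(df, space, population, s, h, grid, roster, landmark):
    if landmark and s > 0:
        df = landmark_transform(df, space, h, s)
    procs = build_cluster_processes(
        df, space, population, grid=grid, cluster_index=roster
    )
    times, dA, Ppath = _engine.transition_curve(procs, s)
    return procs, times, dA, Ppath


def _pooled_grid(df, space):
    ev = df[df["to"] != 0]
    times = np.unique(ev["exit"].to_numpy(dtype=float))
    return times[times <= space.tau]


def _pvalue(draws: np.ndarray, observed: float) -> float:
    """Add-one empirical p-value with conservative tie handling."""
    return float((1 + np.sum(draws >= observed)) / (1 + len(draws)))


def ks_test(
    episodes: pd.DataFrame,
    space: StateSpace,
    target,
    population: str = "acm",
    weight_type: str = "product",
    method: str = "bootstrap",
    n_draws: int = 1000,
    seed=None,
    landmark: bool = True,
    validate: bool = True,
) -> KSTestResult:
    """Two-sample KS-type test between the groups labelled 1 and 2.

    ``target`` is ``("occupation", j)`` or ``("transition", s, h, j)``;
    transition targets with ``s > 0`` use the landmark estimators in each
    group (consistent for non-Markov processes).  Every cluster must
    contain at least one member of each group.  The weight is frozen at
    its data value across bootstrap resamples.
    """
    df = validate_episodes(episodes, space) if validate else episodes
    if "group" not in df.columns:
        raise ValueError("episodes must carry a 'group' column with labels 1 and 2")
    glab = sorted(pd.unique(df["group"]))
    if glab != [1, 2]:
        raise ValueError(f"group labels must be exactly {{1, 2}}, got {glab}")
    roster = sorted(pd.unique(df["cluster"]))
    for g in (1, 2):
        present = set(pd.unique(df.loc[df["group"] == g, "cluster"]))
        missing = [c for c in roster if c not in present]
        if missing:
            raise ValueError(
                f"cluster(s) {missing[:5]} have no members in group {g}; the test "
                "assumes min(M1i, M2i) > 0, i.e. both groups present in every cluster"
            )
    n = len(roster)
    grid = _pooled_grid(df, space)
    d1 = df[df["group"] == 1]
    d2 = df[df["group"] == 2]

    if target[0] == "occupation":
        j = int(target[1])
        p1, times, occ1, c1, dA1, Pp1 = _occupation_pieces(d1, space, population, grid, roster)
        p2, _, occ2, c2, dA2, Pp2 = _occupation_pieces(d2, space, population, grid, roster)
        delta = occ1[:, j - 1] - occ2[:, j - 1]
    elif target[0] == "transition":
        _, s, h, j = target
        s, h, j = float(s), int(h), int(j)
        p1, times, dA1, Pp1 = _transition_pieces(d1, space, population, s, h, grid, roster, landmark)
        p2, _, dA2, Pp2 = _transition_pieces(d2, space, population, s, h, grid, roster, landmark)
        delta = Pp1[:, h - 1, j - 1] - Pp2[:, h - 1, j - 1]
    else:
        raise ValueError("target must be ('occupation', j) or ('transition', s, h, j)")

    W = ks_weight(p1, p2, target, weight_type)
    if target[0] == "transition":
        W = W[len(W) - len(times):] if len(times) < len(W) else W
    K = float(np.max(np.abs(W * delta))) if len(times) else 0.0
    observed = math.sqrt(n) * K

    rng = np.random.default_rng(seed)
    if method in ("bootstrap", "cluster_bootstrap"):
        counts = _engine.bootstrap_counts(
            rng, p1, n_draws,
            require_observed_at_zero=target[0] == "occupation",
        )
        if target[0] == "occupation":
            _, occ1b, _, _, _, _ = _engine.occupation_curve(p1, coef=counts)
            _, occ2b, _, _, _, _ = _engine.occupation_curve(p2, coef=counts)
            db = occ1b[:, :, j - 1] - occ2b[:, :, j - 1]
        else:
            _, _, P1b = _engine.transition_curve(p1, s, coef=counts)
            _, _, P2b = _engine.transition_curve(p2, s, coef=counts)
            db = P1b[:, :, h - 1, j - 1] - P2b[:, :, h - 1, j - 1]
        draws = math.sqrt(n) * np.max(np.abs(W * (db - delta)), axis=1)
    elif method == "multiplier":
        g1 = _group_influence(p1, target, c1 if target[0] == "occupation" else None,
                              Pp1, dA1, times)
        g2 = _group_influence(p2, target, c2 if target[0] == "occupation" else None,
                              Pp2, dA2, times)
        xi = rng.standard_normal((int(n_draws), n))
        Cproc = (xi @ (g1 - g2)) / math.sqrt(n)
        draws = np.max(np.abs(W * Cproc), axis=1)
    else:
        raise ValueError("method must be 'bootstrap' or 'multiplier'")

    return KSTestResult(
        statistic=K,
        scaled_statistic=observed,
        p_value=_pvalue(draws, observed),
        target=tuple(target),
        population=population,
        weight_type=weight_type,
        method=method,
        n_draws=int(n_draws),
        n_clusters=n,
        seed=seed,
        times=times,
        weight=W,
        difference=delta,
    )


def _group_influence(procs, target, c, Ppath, dA, times) -> np.ndarray:
    """Per-cluster influence functions of the targeted path, (n, T)."""
    space = procs.space
    sl = _engine._slice_grid(procs, 0.0 if target[0] == "occupation" else float(target[1]))
    if target[0] == "occupation":
        jdx = int(target[1]) - 1
        entries = [(h - 1, jdx) for h in space.transient if c[h - 1] != 0.0]
    else:
        _, _, h, j = target
        entries = [(int(h) - 1, int(j) - 1)]
    gam = _engine.influence_path(
        procs.dN[:, sl].astype(float),
        procs.Y[:, sl].astype(float),
        procs.weights,
        dA,
        Ppath,
        space,
        entries=entries,
    )
    if target[0] == "occupation":
        gammas = {hdx: gam[:, :, e] for e, (hdx, _) in enumerate(entries)}
        return _occupation_psi(procs, gammas, c, Ppath, jdx)
    return gam[:, :, 0]


def ics_test(
    episodes: pd.DataFrame,
    space: StateSpace,
    j: int,
    weight_type: str = "product",
    method: str = "bootstrap",
    n_draws: int = 1000,
    seed=None,
    validate: bool = True,
) -> KSTestResult:
    """Informative-cluster-size diagnostic for the occupation of state ``j``.

    With noninformative (or constant) cluster size the ACM and TCM
    occupation probabilities coincide, so the weighted sup-difference
    ``sup_t |W(t) {P_j(t) - P'_j(t)}|`` measures informativeness.  The
    null distribution is approximated by cluster-bootstrap (or
    multiplier) realisations of the centred difference, which accounts
    for the strong dependence between the two estimates.  Undefined for
    constant cluster sizes.
    """
    df = validate_episodes(episodes, space) if validate else episodes
    roster = sorted(pd.unique(df["cluster"]))
    n = len(roster)
    grid = _pooled_grid(df, space)
    pa, times, occa, ca, dAa, Ppa = _occupation_pieces(df, space, "acm", grid, roster)
    pt, _, occt, ct, dAt, Ppt = _occupation_pieces(df, space, "tcm", grid, roster)
    if len(np.unique(pa.M)) == 1:
        raise ValueError("ICS test undefined: all clusters have the same size")

    j = int(j)
    delta = occa[:, j - 1] - occt[:, j - 1]
    W = ks_weight(pa, pt, ("occupation", j), weight_type)
    K = float(np.max(np.abs(W * delta))) if len(times) else 0.0
    observed = math.sqrt(n) * K

    rng = np.random.default_rng(seed)
    if method in ("bootstrap", "cluster_bootstrap"):
        counts = _engine.bootstrap_counts(rng, pa, n_draws,
                                          require_observed_at_zero=True)
        _, occab, _, _, _, _ = _engine.occupation_curve(pa, coef=counts)
        _, occtb, _, _, _, _ = _engine.occupation_curve(pt, coef=counts)
        db = occab[:, :, j - 1] - occtb[:, :, j - 1]
        draws = math.sqrt(n) * np.max(np.abs(W * (db - delta)), axis=1)
    elif method == "multiplier":
        ga = _group_influence(pa, ("occupation", j), ca, Ppa, dAa, times)
        gt = _group_influence(pt, ("occupation", j), ct, Ppt, dAt, times)
        xi = rng.standard_normal((int(n_draws), n))
        draws = np.max(np.abs(W * ((xi @ (ga - gt)) / math.sqrt(n))), axis=1)
    else:
        raise ValueError("method must be 'bootstrap' or 'multiplier'")

    return KSTestResult(
        statistic=K,
        scaled_statistic=observed,
        p_value=_pvalue(draws, observed),
        target=("ics_occupation", j),
        population="acm_vs_tcm",
        weight_type=weight_type,
        method=method,
        n_draws=int(n_draws),
        n_clusters=n,
        seed=seed,
        times=times,
        weight=W,
        difference=delta,
    )
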