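"""Population-averaged estimators for clustered multistate data.

The estimators follow the scikit-learn protocol: construct with the model
description, ``fit`` on a long-format episode table (a pandas DataFrame),
then read step-function results from fitted attributes or evaluate them at
arbitrary times with ``predict``.

Two target populations are supported.  Over the *all cluster members*
(ACM) population every subject counts equally, so larger clusters dominate
(cluster weight ``w_i = 1``).  Over the *typical cluster member* (TCM)
population every cluster counts equally (``w_i = 1/M_i``).  With
informative cluster size the two sets of probabilities genuinely differ;
with constant cluster size they coincide.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _engine
from .episodes import landmark_transform, observed_at_zero, validate_episodes
from .processes import ClusterProcesses, build_cluster_processes
from .state_space import StateSpace

__all__ = [
    "CumulativeIntensity",
    "TransitionProbability",
    "StateOccupation",
    "cumulative_intensity",
    "product_integral",
    "transition_probability",
    "state_occupation",
    "pi_hat",
]


def pi_hat(processes: ClusterProcesses) -> float:
    """Estimated probability of being under observation at time zero.

    ``pi_hat = n^{-1} sum_i M_i^{-1} sum_{h transient} Y_i.,h(0+)``;
    equals one in the absence of left truncation.  Raises when no subject
    is under observation at time zero.
    """
    _, pi = _engine.occupation_weights(processes)
    return float(pi)


class _EpisodeFitter(BaseEstimator):
    """Shared fitting plumbing: validation and process construction."""

    def _space(self) -> StateSpace:
        if self.state_space is None:
            raise ValueError("state_space must be provided")
        return self.state_space

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.validate:
            return validate_episodes(X, self._space())
        return X


class CumulativeIntensity(_EpisodeFitter):
    """Population-averaged cumulative transition intensities.

    The jump at a pooled transition time ``u`` is the weighted
    Nelson-Aalen ratio ``sum_i w_i dN_i.,hj(u) / sum_i w_i Y_i.,h(u)``,
    with ``w_i`` the population weight; times with a zero at-risk sum
    contribute no jump.

    Attributes (after ``fit``)
    --------------------------
    times_ : (T,) array of pooled transition times
    jumps_ : (T, C) jump sizes per transition (column order
        ``state_space.transitions``)
    cum_ : (T, C) cumulative intensities
    risk_ : (T, k) pooled weighted at-risk paths
    processes_ : the underlying :class:`ClusterProcesses`
    """

    def __init__(self, state_space=None, population="acm", t_max=None, validate=True):
        self.state_space = state_space
        self.population = population
        self.t_max = t_max
        self.validate = validate

    def fit(self, X: pd.DataFrame, y=None):
        df = self._prepare(X)
        procs = build_cluster_processes(
            df, self._space(), self.population, t_max=self.t_max
        )
        wdN, wY = procs.aggregate()
        dA = _engine.intensity_jumps(wdN, wY, procs.space)
        self.episodes_ = df
        self.processes_ = procs
        self.times_ = procs.times
        self.jumps_ = dA
        self.cum_ = np.cumsum(dA, axis=0)
        self.risk_ = wY
        return self

    def predict(self, times) -> np.ndarray:
        """Cumulative intensities ``A_hj(t)`` at arbitrary times, (len, C)."""
        C = len(self._space().transitions)
        return _engine.step_eval(self.times_, self.cum_, times, np.zeros(C))

    def curve(self, h: int, j: int) -> np.ndarray:
        """Cumulative intensity path for one transition on ``times_``."""
        c = self._space().transitions.index((int(h), int(j)))
        return self.cum_[:, c]


class TransitionProbability(_EpisodeFitter):
    """Aalen-Johansen-type transition probability matrices ``P(s, t)``.

    The matrix path is the product integral of the population-averaged
    cumulative intensity matrix over ``(s, t]``.  For non-Markov processes
    and ``s > 0``, set ``landmark`` to the origin state ``h``: estimation
    then uses only subjects in state ``h`` and under observation just
    after ``s`` (the landmark device), which restores consistency.

    Attributes (after ``fit``)
    --------------------------
    times_ : (T,) grid times in ``(s, tau]``
    prob_ : (T, k, k) row-stochastic matrices ``P(s, t)``
    n_clusters_ : number of clusters contributing
    processes_ : underlying :class:`ClusterProcesses`
    """

    def __init__(
        self,
        state_space=None,
        population="acm",
        origin=0.0,
        landmark=None,
        t_max=None,
        validate=True,
    ):
        self.state_space = state_space
        self.population = population
        self.origin = origin
        self.landmark = landmark
        self.t_max = t_max
        self.validate = validate

    def fit(self, X: pd.DataFrame, y=None):
        space = self._space()
        df = self._prepare(X)
        if self.landmark is not None:
            df = landmark_transform(df, space, self.landmark, self.origin)
        procs = build_cluster_processes(df, space, self.population, t_max=self.t_max)
        times, dA, Ppath = _engine.transition_curve(procs, self.origin)
        self.episodes_ = df
        self.processes_ = procs
        self.times_ = times
        self.jumps_ = dA
        self.prob_ = Ppath
        self.n_clusters_ = procs.n
        self._influence_cache = {}
        return self

    def predict(self, times) -> np.ndarray:
        """Matrices ``P(origin, t)``, shape (len, k, k); identity at ``t <= origin``."""
        return _engine.step_eval(self.times_, self.prob_, times, np.eye(self._space().k))

    def curve(self, h: int, j: int) -> np.ndarray:
        """Path of ``P_hj(origin, t)`` on ``times_``."""
        return self.prob_[:, int(h) - 1, int(j) - 1]

    def influence_path(self, entries=None) -> np.ndarray:
        """Estimated per-cluster influence functions on ``times_``.

        Shape ``(n, T, k, k)``, or ``(n, T, E)`` when ``entries`` (a list
        of zero-based ``(h, j)`` index pairs) restricts the recorded
        matrix entries.  Results are cached per entry selection.
        """
        key = None if entries is None else tuple(entries)
        if key not in self._influence_cache:
            procs = self.processes_
            sl = _engine._slice_grid(procs, self.origin)
            self._influence_cache[key] = _engine.influence_path(
                procs.dN[:, sl].astype(float),
                procs.Y[:, sl].astype(float),
                procs.weights,
                self.jumps_,
                self.prob_,
                procs.space,
                entries=entries,
            )
        return self._influence_cache[key]


class StateOccupation(_EpisodeFitter):
    """Population-averaged state occupation probabilities ``P_j(t)``.

    ``P_j(t) = sum_h c_h P_hj(0, t)`` where the weights ``c_h`` estimate
    the initial state distribution from the at-risk counts just after
    time zero, corrected for left truncation through ``pi_hat``.  Under
    left truncation with a possibly non-Markov process, the transition
    part is computed from the subset of subjects under observation at
    time zero, which keeps the estimator consistent.

    Attributes (after ``fit``)
    --------------------------
    times_ : (T,) grid times
    occupation_ : (T, k) occupation probability paths
    pi_ : estimated probability of being under observation at time zero
    initial_weights_ : (k,) the weights ``c_h``
    prob_path_ : (T, k, k) the underlying ``P(0, t)`` path
    """

    def __init__(self, state_space=None, population="acm", t_max=None, validate=True):
        self.state_space = state_space
        self.population = population
        self.t_max = t_max
        self.validate = validate

    def fit(self, X: pd.DataFrame, y=None):
        space = self._space()
        df = self._prepare(X)
        first_entry = df.groupby(["cluster", "id"])["entry"].transform("min")
        truncated = bool((first_entry > 0).any())
        sub = df[first_entry == 0.0] if truncated else None
        procs = build_cluster_processes(
            df, space, self.population, t_max=self.t_max, counting_subjects=sub
        )
        times, occ, pi, c, dA, Ppath = _engine.occupation_curve(procs)
        self.episodes_ = df
        self.processes_ = procs
        self.times_ = times
        self.occupation_ = occ
        self.pi_ = float(pi)
        self.initial_weights_ = c
        self.jumps_ = dA
        self.prob_path_ = Ppath
        self.truncated_ = truncated
        self._influence_cache = {}
        return self

    def predict(self, times) -> np.ndarray:
        """Occupation probabilities at arbitrary times, shape (len, k)."""
        return _engine.step_eval(self.times_, self.occupation_, times, self.initial_weights_)

    def curve(self, j: int) -> np.ndarray:
        """Path of ``P_j(t)`` on ``times_``."""
        return self.occupation_[:, int(j) - 1]

    def influence_path(self, entries=None) -> np.ndarray:
        """Per-cluster influence functions of the transition part.

        Shape ``(n, T, k, k)``, or ``(n, T, E)`` for a restricted entry
        selection; cached per selection.
        """
        key = None if entries is None else tuple(entries)
        if key not in self._influence_cache:
            procs = self.processes_
            sl = _engine._slice_grid(procs, 0.0)
            self._influence_cache[key] = _engine.influence_path(
                procs.dN.astype(float)[:, sl],
                procs.Y.astype(float)[:, sl],
                procs.weights,
                self.jumps_,
                self.prob_path_,
                procs.space,
                entries=entries,
            )
        return self._influence_cache[key]


def product_integral(intensity: CumulativeIntensity, s: float = 0.0) -> TransitionProbability:
    """Transition probabilities from a fitted cumulative intensity.

    Computes ``P(s, t) = prod_{s < u <= t} (I + dA(u))`` over the jump
    grid of ``intensity``, reusing its underlying cluster processes, and
    returns a fitted :class:`TransitionProbability`.
    """
    procs = intensity.processes_
    est = TransitionProbability(
        intensity.state_space, procs.population, origin=s, validate=False
    )
    est.episodes_ = getattr(intensity, "episodes_", None)
    est.processes_ = procs
    times, dA, Ppath = _engine.transition_curve(procs, s)
    est.times_, est.jumps_, est.prob_ = times, dA, Ppath
    est.n_clusters_ = procs.n
    est._influence_cache = {}
    return est


def cumulative_intensity(episodes, state_space, population="acm", **kw) -> CumulativeIntensity:
    """Fit a :class:`CumulativeIntensity` estimator (thin wrapper)."""
    return CumulativeIntensity(state_space, population, **kw).fit(episodes)


def transition_probability(
    episodes, state_space, s=0.0, population="acm", landmark=None, **kw
) -> TransitionProbability:
    """Fit a :class:`TransitionProbability` estimator from origin ``s``."""
    return TransitionProbability(
        state_space, population, origin=s, landmark=landmark, **kw
    ).fit(episodes)


def state_occupation(episodes, state_space, population="acm", **kw) -> StateOccupation:
    """Fit a :class:`StateOccupation` estimator (thin wrapper)."""
    return StateOccupation(state_space, population, **kw).fit(episodes)
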