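"""Per-cluster counting and at-risk processes on the pooled jump grid.

The estimators only ever see the data through the cluster-level aggregates
``N_{i.,hj}(t) = sum_m N_{im,hj}(t)`` (observed h->j transitions) and
``Y_{i.,h}(t) = sum_m Y_{im,h}(t)`` (members at state h and under
observation just before t), together with the cluster sizes ``M_i``.  This
module turns a validated episode table into dense arrays of these
quantities evaluated on the pooled grid of observed transition times,
which is all later steps (estimation, influence functions, bootstrap)
operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .episodes import CENSORED, cluster_sizes
from .state_space import StateSpace

__all__ = ["ClusterProcesses", "build_cluster_processes"]


@dataclass
class ClusterProcesses:
    """Cluster-level processes evaluated on the pooled jump-time grid.

    Attributes
    ----------
    space : StateSpace
    population : str
        ``"acm"`` (all cluster members, weight 1) or ``"tcm"`` (typical
        cluster member, weight ``1/M_i``).
    times : (T,) float array
        Sorted distinct observed transition times.
    dN : (n, T, C) int array
        Transition counts per cluster, time and transition (column order
        ``space.transitions``).
    Y : (n, T, k) int array
        At-risk counts per cluster, time and state, evaluated just before
        each grid time (``entry < t <= exit``).
    Y0p : (n, k) int array
        At-risk counts just after time zero (episodes with ``entry == 0``).
    M : (n,) int array
        Cluster sizes.
    cluster_ids : list
        Original cluster labels, aligned with the first axis.
    """

    space: StateSpace
    population: str
    times: np.ndarray
    dN: np.ndarray
    Y: np.ndarray
    Y0p: np.ndarray
    M: np.ndarray
    cluster_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        """Number of clusters."""
        return len(self.M)

    @property
    def constant_size(self) -> bool:
        """Whether all clusters share one size (TCM then coincides with ACM)."""
        return len(np.unique(self.M)) <= 1

    @property
    def weights(self) -> np.ndarray:
        """Population weights ``w_i``: 1 (ACM) or ``1/M_i`` (TCM).

        With constant cluster size the common inverse-size factor cancels
        from every weighted ratio, so unit weights are returned for both
        populations; this keeps the two estimates identical to the bit.
        """
        if self.population == "acm" or self.constant_size:
            return np.ones(self.n)
        return 1.0 / self.M.astype(float)

    def aggregate(self, coef: Optional[np.ndarray] = None):
        """Weighted cluster aggregates of ``dN`` and ``Y``.

        ``coef`` (optional, shape ``(n,)`` or ``(B, n)``) holds resampling
        multiplicities; population weights are applied on top.  Returns
        ``(wdN, wY)`` with leading batch axes matching ``coef``.
        """
        w = self.weights
        c = w if coef is None else np.asarray(coef) * w
        wdN = np.tensordot(c, self.dN, axes=([-1], [0]))
        wY = np.tensordot(c, self.Y, axes=([-1], [0]))
        return wdN, wY

def build_cluster_processes(
    episodes: pd.DataFrame,
    space: StateSpace,
    population: str = "acm",
    t_max: Optional[float] = None,
    subject_as_cluster: bool = False,
    counting_subjects: Optional[pd.DataFrame] = None,
    grid: Optional[np.ndarray] = None,
    cluster_index: Optional[list] = None,
) -> ClusterProcesses:
    """Aggregate a validated episode table to per-cluster processes.

    Parameters
    ----------
    episodes : DataFrame
        Validated episode table.
    population : {"acm", "tcm"}
        Which population weight the processes will carry.
    t_max : float, optional
        Truncate the jump grid at this time (estimates are step functions,
        so later evaluation below ``t_max`` is unaffected).
    subject_as_cluster : bool
        Treat every subject as its own cluster of size one (the working
        independence view used by the naive variance estimator).
    counting_subjects : DataFrame, optional
        If given, the counting/at-risk arrays ``dN``/``Y`` are accumulated
        only from these rows (a sub-table of ``episodes``), while cluster
        sizes and time-zero at-risk counts still come from the full table.
        Used for state occupation estimation under left truncation, which
        must restrict the transition-probability part to subjects under
        observation at time zero.
    grid : array, optional
        Use this jump-time grid instead of the table's own transition
        times; needed when several tables (e.g. the two groups of a
        two-sample test) must share one grid.
    cluster_index : list, optional
        Full cluster roster to align the first axis with; clusters absent
        from the table get zero processes (their size defaults to one).
        Needed when several tables must share one cluster indexing.
    """
    if population not in ("acm", "tcm"):
        raise ValueError("population must be 'acm' or 'tcm'")
    df = episodes
    k = space.k
    trans = space.transitions
    C = len(trans)

    if subject_as_cluster:
        key = list(zip(df["cluster"].to_numpy(), df["id"].to_numpy()))
        codes, uniques = pd.factorize(pd.Index(key))
        sizes = np.ones(len(uniques), dtype=np.int64)
        ids = list(uniques)
    elif cluster_index is not None:
        ids = list(cluster_index)
        lookup = {c: i for i, c in enumerate(ids)}
        codes = np.array([lookup[c] for c in df["cluster"].to_numpy()])
        msizes = cluster_sizes(df)
        sizes = np.array([int(msizes.get(c, 1)) for c in ids], dtype=np.int64)
    else:
        codes, uniques = pd.factorize(df["cluster"], sort=True)
        ids = list(uniques)
        msizes = cluster_sizes(df)
        sizes = np.array([msizes[c] for c in ids], dtype=np.int64)
    n = len(ids)

    sub = df if counting_subjects is None else counting_subjects
    if counting_subjects is not None:
        # align sub-table rows with the full-table cluster codes
        lookup = {c: i for i, c in enumerate(ids)}
        sub_codes = np.array([lookup[c] for c in sub["cluster"].to_numpy()])
    else:
        sub_codes = codes

    entry = sub["entry"].to_numpy(dtype=float)
    exit_ = sub["exit"].to_numpy(dtype=float)
    from_ = sub["from"].to_numpy()
    to = sub["to"].to_numpy()

    is_event = to != CENSORED
    if grid is not None:
        times = np.asarray(grid, dtype=float)
    else:
        times = np.unique(exit_[is_event])
    if t_max is not None:
        times = times[times <= t_max]
    T = len(times)

    dN = np.zeros((n, T, C), dtype=np.int32)
    Y = np.zeros((n, T, k), dtype=np.int32)

    if T:
        # transition counts at exact exit times
        tri = {t: c for c, t in enumerate(trans)}
        ev = is_event & (exit_ <= times[-1])
        ti = np.searchsorted(times, exit_[ev])
        on_grid = times[np.minimum(ti, T - 1)] == exit_[ev]
        ti = ti[on_grid]
        cols = np.array(
            [tri[(h, j)] for h, j in zip(from_[ev][on_grid], to[ev][on_grid])],
            dtype=np.intp,
        )
        np.add.at(dN, (sub_codes[ev][on_grid], ti, cols), 1)

        # at-risk counts via interval difference accumulation:
        # episode contributes to grid times with entry < t <= exit
        lo = np.searchsorted(times, entry, side="right")
        hi = np.searchsorted(times, exit_, side="right")
        D = np.zeros((n, T + 1, k), dtype=np.int32)
        hidx = from_ - 1
        np.add.at(D, (sub_codes, lo, hidx), 1)
        np.add.at(D, (sub_codes, hi, hidx), -1)
        Y = np.cumsum(D, axis=1)[:, :T, :]

    # at-risk just after time 0: full table, episodes starting at 0
    fentry = df["entry"].to_numpy(dtype=float)
    ffrom = df["from"].to_numpy()
    Y0p = np.zeros((n, k), dtype=np.int64)
    z = fentry == 0.0
    np.add.at(Y0p, (codes[z], ffrom[z] - 1), 1)

    return ClusterProcesses(
        space=space,
        population=population,
        times=times,
        dN=dN,
        Y=Y,
        Y0p=Y0p,
        M=sizes,
        cluster_ids=ids,
    )
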