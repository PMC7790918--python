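"""Long-format episode tables: reading, validation, landmarking.

An episode table holds one row per at-risk episode of a subject:
``(cluster, id, [group], entry, exit, from, to)``.  The subject occupies
state ``from`` on the interval ``(entry, exit]``; at ``exit`` it either
moves to state ``to`` or is right-censored (``to`` is the token ``"cens"``
on disk, the integer 0 in memory).  Delayed entry (left truncation) is
expressed by a first ``entry`` larger than zero.

The at-risk convention is that of counting-process theory: a subject is at
risk in state ``h`` at time ``t`` when ``entry < t <= exit``, i.e. "at
state h and under observation just before t".  A censoring tied with
another subject's transition therefore leaves the censored subject in the
risk set for that transition.
"""

from __future__ import annotations

import io
from typing import Optional

import numpy as np
import pandas as pd

from .state_space import StateSpace

__all__ = [
    "CENSORED",
    "CENSORED_TOKEN",
    "EpisodeValidationError",
    "read_episodes",
    "write_episodes",
    "validate_episodes",
    "landmark_transform",
    "cluster_sizes",
    "observed_at_zero",
]

#: integer code used for right censoring in the in-memory ``to`` column
CENSORED = 0
#: token used for right censoring in delimited files
CENSORED_TOKEN = "cens"

REQUIRED_COLUMNS = ("cluster", "id", "entry", "exit", "from", "to")


class EpisodeValidationError(ValueError):
    """Raised when an episode table violates the data contract."""


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce column dtypes and sort by (cluster, id, entry)."""
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EpisodeValidationError(f"missing required columns: {missing}")
    to = df["to"]
    if to.dtype == object:
        to = to.where(to.astype(str) != CENSORED_TOKEN, CENSORED)
    df["to"] = pd.to_numeric(to).astype(np.int64)
    df["from"] = pd.to_numeric(df["from"]).astype(np.int64)
    for c in ("entry", "exit"):
        df[c] = pd.to_numeric(df[c]).astype(np.float64)
    if "group" in df.columns:
        df["group"] = pd.to_numeric(df["group"]).astype(np.int64)
    attrs = dict(df.attrs)
    df = df.sort_values(["cluster", "id", "entry"], kind="mergesort").reset_index(drop=True)
    df.attrs.update(attrs)
    return df


def validate_episodes(df: pd.DataFrame, space: StateSpace) -> pd.DataFrame:
    """Validate an episode table against the data contract and state space.

    Checks, vectorised over rows:

    * ``entry < exit`` and nonnegative times;
    * per subject, episodes are contiguous (next entry equals previous
      exit) and states chain (next ``from`` equals previous ``to``);
    * a censored row is the subject's last;
    * every transition is allowed by the model graph and no episode starts
      in an absorbing state.

    Returns the normalised, sorted table.  Raises
    :class:`EpisodeValidationError` naming the first offending row.
    """
    df = _normalise(df)
    if len(df) == 0:
        return df

    entry = df["entry"].to_numpy()
    exit_ = df["exit"].to_numpy()
    from_ = df["from"].to_numpy()
    to = df["to"].to_numpy()

    def offend(mask, message):
        if mask.any():
            row = int(np.flatnonzero(mask)[0])
            raise EpisodeValidationError(f"row {row}: {message}")

    offend(entry < 0, "negative entry time")
    offend(exit_ <= entry, "exit <= entry")

    transient = set(space.transient)
    offend(~np.isin(from_, list(transient)), "transition out of absorbing state"
           if set(from_) & space.absorbing else "unknown source state")
    allowed = set(space.transitions)
    bad = np.array(
        [t != CENSORED and (h, t) not in allowed for h, t in zip(from_, to)]
    )
    offend(bad, "transition not allowed by the model graph")

    # within-subject chaining
    same = (
        (df["cluster"].to_numpy()[1:] == df["cluster"].to_numpy()[:-1])
        & (df["id"].to_numpy()[1:] == df["id"].to_numpy()[:-1])
    )
    nxt = np.zeros(len(df), dtype=bool)
    nxt[1:] = same
    prev_exit = np.roll(exit_, 1)
    prev_to = np.roll(to, 1)
    offend(nxt & (entry != prev_exit), "episodes not contiguous (entry != previous exit)")
    offend(nxt & (prev_to == CENSORED), "censored row is not the subject's last")
    offend(nxt & (from_ != prev_to), "state chain broken (from != previous to)")
    return df


def read_episodes(source, space: StateSpace, sep: Optional[str] = None) -> pd.DataFrame:
    """Read and validate a delimited episode table (comma or tab).

    ``source`` may be a path or an open text stream.  The header must name
    the columns ``cluster, id, entry, exit, from, to`` (``group``
    optional); ``to`` uses state labels or the token ``"cens"``.
    """
    if sep is None:
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        header = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in header else ","
        source = io.StringIO(text)
    df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    return validate_episodes(df, space)


def write_episodes(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write an episode table with censoring rendered as ``"cens"``."""
    out = df.copy()
    out["to"] = out["to"].astype(object)
    out.loc[out["to"] == CENSORED, "to"] = CENSORED_TOKEN
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def cluster_sizes(df: pd.DataFrame) -> pd.Series:
    """Cluster sizes ``M_i``: number of distinct subjects per cluster.

    When the table is the result of :func:`landmark_transform`, the sizes
    of the *original* table are returned (carried in ``df.attrs``), since
    the inverse-size weights of the typical-cluster-member population are
    defined through the full cluster sizes.
    """
    stored = df.attrs.get("cluster_size")
    if stored is not None:
        return pd.Series(stored)
    return df.groupby("cluster")["id"].nunique()


def observed_at_zero(df: pd.DataFrame) -> pd.DataFrame:
    """Sub-table of subjects under observation at time 0 (first entry = 0).

    Used for state occupation estimation under left truncation, where
    consistency for possibly non-Markov processes requires restricting to
    the subset under observation at the time origin.
    """
    first_entry = df.groupby(["cluster", "id"])["entry"].transform("min")
    out = df[first_entry == 0.0].reset_index(drop=True)
    out.attrs["cluster_size"] = cluster_sizes(df).to_dict()
    return out


def landmark_transform(df: pd.DataFrame, space: StateSpace, h: int, s: float) -> pd.DataFrame:
    """Restrict to subjects in state ``h`` and under observation just after ``s``.

    Implements the landmark device for non-Markov processes: estimation of
    ``P(s, t)`` from state ``h`` uses the modified processes
    ``N(t) * Y_h(s+)`` and ``Y(t) * Y_h(s+)``, which amounts to keeping
    exactly the subjects with an episode in state ``h`` covering ``s+``
    (``entry <= s < exit``).  Clusters losing all subjects are dropped;
    the original cluster sizes are retained in ``attrs['cluster_size']``
    for inverse-size weighting of the remaining members.

    Raises ``ValueError("empty landmark set")`` when nobody qualifies.
    The operation is idempotent at fixed ``(h, s)``.
    """
    if h in space.absorbing:
        raise ValueError(f"landmark state {h} must be transient")
    if not s < space.tau:
        raise ValueError("landmark time must precede the horizon tau")
    sizes = cluster_sizes(df).to_dict()
    at_h = (
        (df["from"].to_numpy() == int(h))
        & (df["entry"].to_numpy() <= s)
        & (df["exit"].to_numpy() > s)
    )
    keep_keys = set(map(tuple, df.loc[at_h, ["cluster", "id"]].itertuples(index=False)))
    if not keep_keys:
        raise ValueError("empty landmark set")
    mask = [
        (c, i) in keep_keys
        for c, i in zip(df["cluster"].to_numpy(), df["id"].to_numpy())
    ]
    out = df[np.asarray(mask)].reset_index(drop=True)
    out.attrs["cluster_size"] = {
        c: sizes[c] for c in pd.unique(out["cluster"])
    }
    return out
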