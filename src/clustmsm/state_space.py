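"""Finite state-space description for multistate processes.

A multistate process moves among a finite set of states ``S = {1, ..., k}``
along a directed graph of allowed instantaneous transitions.  A subset of
states is absorbing (once entered, never left; e.g. death).  The state
space also carries the administrative horizon ``tau``, the right end of the
time window on which estimation is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable


__all__ = ["StateSpace", "reachable_transient_states", "illness_death"]


@dataclass(frozen=True)
class StateSpace:
    """States, absorbing set, allowed transitions and time horizon.

    Parameters
    ----------
    states : tuple of int
        Ordered state labels ``1..k``.
    absorbing : frozenset of int
        States with no outgoing transitions.
    transitions : tuple of (int, int)
        Allowed ordered pairs ``(h, j)`` with ``h != j``; every source must
        be transient.
    tau : float
        Administrative horizon; must be positive.
    """

    states: tuple = field(default=())
    absorbing: frozenset = field(default=frozenset())
    transitions: tuple = field(default=())
    tau: float = 1.0

    def __post_init__(self):
        states = tuple(int(s) for s in self.states)
        if states != tuple(range(1, len(states) + 1)):
            raise ValueError("states must be the ordered labels 1..k")
        object.__setattr__(self, "states", states)
        absorbing = frozenset(int(s) for s in self.absorbing)
        if not absorbing <= set(states):
            raise ValueError("absorbing states must be a subset of the states")
        object.__setattr__(self, "absorbing", absorbing)
        transitions = tuple(sorted((int(h), int(j)) for h, j in self.transitions))
        for h, j in transitions:
            if h == j:
                raise ValueError(f"self-transition ({h}, {j}) is not allowed")
            if h not in states or j not in states:
                raise ValueError(f"transition ({h}, {j}) uses unknown states")
            if h in absorbing:
                raise ValueError(f"transition out of absorbing state {h}")
        object.__setattr__(self, "transitions", transitions)
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        object.__setattr__(self, "tau", float(self.tau))

    # -- basic structure ---------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def transient(self) -> tuple:
        """Transient states (complement of the absorbing set), ordered."""
        return tuple(s for s in self.states if s not in self.absorbing)

    def index(self, state: int) -> int:
        """Zero-based index of a state label."""
        return int(state) - 1

    def is_allowed(self, h: int, j: int) -> bool:
        return (int(h), int(j)) in set(self.transitions)

    def successors(self, h: int) -> tuple:
        return tuple(j for (a, j) in self.transitions if a == h)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "absorbing": sorted(self.absorbing),
            "transitions": [list(t) for t in self.transitions],
            "tau": self.tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpace":
        states = d.get("states")
        if isinstance(states, int):  # allow {"states": k}
            states = list(range(1, states + 1))
        return cls(
            states=tuple(states),
            absorbing=frozenset(d.get("absorbing", ())),
            transitions=tuple(tuple(t) for t in d["transitions"]),
            tau=d.get("tau", 1.0),
        )

    @classmethod
    def from_json(cls, source) -> "StateSpace":
        """Read a state space from a JSON file path or open stream."""
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def reachable_transient_states(space: StateSpace, h: int, j: int) -> set:
    """Transient states that can be visited during an ``h -> j`` transition.

    Returns ``L(h, j)``: the transient states ``d`` lying on some directed
    path ``h -> ... -> d -> ... -> j`` in the transition graph.  ``h`` is
    always included when the pair is connected; ``j`` is included only when
    it is transient.  If ``j`` is unreachable from ``h`` the empty set is
    returned with a warning.
    """
    h, j = int(h), int(j)
    if h in space.absorbing:
        raise ValueError(f"state {h} is absorbing; L(h, j) requires transient h")

    adj: dict = {s: [] for s in space.states}
    radj: dict = {s: [] for s in space.states}
    for a, b in space.transitions:
        adj[a].append(b)
        radj[b].append(a)

    def closure(start, graph):
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in graph[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    forward = closure(h, adj)
    backward = closure(j, radj)
    if j not in forward:
        warnings.warn(f"state {j} is unreachable from state {h}", stacklevel=2)
        return set()
    on_path = forward & backward
    return {d for d in on_path if d not in space.absorbing}


def illness_death(tau: float = 3.0) -> StateSpace:
    """The irreversible illness-death model: 1=healthy, 2=ill, 3=dead."""
    return StateSpace(
        states=(1, 2, 3),
        absorbing=frozenset({3}),
        transitions=((1, 2), (1, 3), (2, 3)),
        tau=tau,
    )
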