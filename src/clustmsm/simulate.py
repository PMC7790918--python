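"""Clustered frailty illness-death simulator with informative cluster size.

The generator emulates a multicenter study: ``n`` clusters (centers) with
random sizes ``M_i ~ DiscreteUniform(a, b)`` and gamma(1, 1) cluster
frailties ``v_i``.  Conditionally on ``(v_i, m_i)`` each member follows a
time-homogeneous illness-death process (1 = healthy, 2 = ill, 3 = dead)
with cumulative intensities linear in time,

    A_12(t) = [0.25 + 0.25 I(m_i <= E M)] v_i t,
    A_13(t) = 0.25 v_i t,      A_23(t) = 0.5 v_i t,

so the marginal process is non-Markov (frailty mixing) and the intensity
shift in small clusters makes cluster size informative.  Right-censoring
times are U(0, 3); optional left-truncation times are Beta(1, 2), or zero
with probability 2/3 and Beta(1, 2) otherwise.  A two-arm variant adds
``0.5 v_i t`` to the healthy-to-ill intensity in arm 2 with 1:1
within-cluster allocation.

Because the frailty is gamma with unit shape and scale (Laplace transform
``(1 + s)^{-1}``), the population-averaged occupation and transition
probabilities have closed forms, used as ground truth in the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "simulate_trial",
    "outcome_mix",
    "state1_at_risk_fraction",
    "true_occupation",
    "true_transition_12",
    "true_probability",
    "followup_percentile",
]


@dataclass(frozen=True)
class SimConfig:
    """Full description of the simulated multicenter illness-death study."""

    n_clusters: int = 80
    size_range: tuple = (10, 30)
    slope_12: float = 0.25
    slope_13: float = 0.25
    slope_23: float = 0.5
    ics_bump: float = 0.25
    arm_effect: float = 0.0
    two_arm: bool = False
    censor_max: float = 3.0
    truncation: str = "none"  # none | beta | mixed
    tau: float = 3.0

    def __post_init__(self):
        a, b = self.size_range
        if not (1 <= a <= b):
            raise ValueError("size_range must satisfy 1 <= a <= b")
        for s in (self.slope_12, self.slope_13, self.slope_23):
            if not s > 0:
                raise ValueError("intensity slopes must be positive")
        if self.truncation not in ("none", "beta", "mixed"):
            raise ValueError("truncation must be 'none', 'beta' or 'mixed'")

    @property
    def expected_size(self) -> float:
        """Exact mean of the declared cluster-size distribution."""
        a, b = self.size_range
        return (a + b) / 2.0


def _simulate_latent(config: SimConfig, rng: np.random.Generator, n_clusters=None):
    """Latent per-subject quantities: frailty, arm, event, censor, entry."""
    n = config.n_clusters if n_clusters is None else n_clusters
    a, b = config.size_range
    M = rng.integers(a, b + 1, n)
    v = rng.gamma(1.0, 1.0, n)
    cl = np.repeat(np.arange(n), M)
    nsub = len(cl)
    m = M[cl]
    vi = v[cl]

    if config.two_arm:
        starts = np.concatenate(([0], np.cumsum(M)[:-1]))
        pos = np.arange(nsub) - starts[cl]
        offset = rng.integers(0, 2, n)
        arm = 1 + ((pos + offset[cl]) % 2)
    else:
        arm = np.ones(nsub, dtype=np.int64)

    bump = config.ics_bump * (m <= config.expected_size)
    h12 = (config.slope_12 + config.arm_effect * (arm == 2) + bump) * vi
    h13 = config.slope_13 * vi
    h23 = config.slope_23 * vi

    tot = h12 + h13
    T1 = rng.exponential(1.0 / tot)
    dest = np.where(rng.random(nsub) < h13 / tot, 3, 2)
    death = np.where(dest == 3, T1, T1 + rng.exponential(1.0 / h23))

    C = rng.uniform(0.0, config.censor_max, nsub)
    if config.truncation == "none":
        L = np.zeros(nsub)
    elif config.truncation == "beta":
        L = rng.beta(1.0, 2.0, nsub)
    else:
        L = np.where(rng.random(nsub) < 2.0 / 3.0, 0.0, rng.beta(1.0, 2.0, nsub))

    return {
        "cluster": cl, "size": m, "frailty": vi, "arm": arm,
        "T1": T1, "dest": dest, "death": death, "C": C, "L": L,
    }


def _latent_to_episodes(lat: dict, config: SimConfig) -> pd.DataFrame:
    """Observed episode table; subjects never under observation are absent."""
    cl, arm = lat["cluster"], lat["arm"]
    T1, dest, death, C, L = lat["T1"], lat["dest"], lat["death"], lat["C"], lat["L"]
    sid = np.arange(len(cl))

    rows = []
    # healthy-state episodes: entered while in state 1
    in1 = (L < T1) & (L < C)
    exit1 = np.minimum(T1, C)
    to1 = np.where(T1 <= C, dest, 0)
    rows.append(dict(cluster=cl[in1], id=sid[in1], group=arm[in1],
                     entry=L[in1], exit=exit1[in1],
                     frm=np.ones(in1.sum(), dtype=np.int64), to=to1[in1]))
    # illness-state episodes (entered at transition or by delayed entry)
    e2 = np.maximum(L, T1)
    x2 = np.minimum(death, C)
    in2 = (dest == 2) & (e2 < x2)
    to2 = np.where(death <= C, 3, 0)
    rows.append(dict(cluster=cl[in2], id=sid[in2], group=arm[in2],
                     entry=e2[in2], exit=x2[in2],
                     frm=np.full(in2.sum(), 2, dtype=np.int64), to=to2[in2]))

    df = pd.DataFrame({
        "cluster": np.concatenate([r["cluster"] for r in rows]),
        "id": np.concatenate([r["id"] for r in rows]),
        "group": np.concatenate([r["group"] for r in rows]),
        "entry": np.concatenate([r["entry"] for r in rows]),
        "exit": np.concatenate([r["exit"] for r in rows]),
        "from": np.concatenate([r["frm"] for r in rows]),
        "to": np.concatenate([r["to"] for r in rows]),
    })
    if not config.two_arm:
        df = df.drop(columns="group")
    df = df.sort_values(["cluster", "id", "entry"], kind="mergesort").reset_index(drop=True)
    return df


def simulate_trial(config: SimConfig, seed=None, return_latent: bool = False):
    """Simulate one study; returns the observed episode table.

    With ``return_latent=True`` also returns the latent per-subject
    arrays (frailties, uncensored event times, censoring and truncation
    times), useful for diagnostics and oracle checks.
    """
    rng = np.random.default_rng(seed)
    lat = _simulate_latent(config, rng)
    df = _latent_to_episodes(lat, config)
    if return_latent:
        return df, lat
    return df


def outcome_mix(episodes: pd.DataFrame) -> dict:
    """Observed outcome classification of subjects, as percentages.

    A subject counts as ``censored`` if right-censored while healthy, as
    ``illness`` if observed to enter state 2 (whether or not later dying),
    and as ``direct_death`` if observed to move 1 -> 3 directly; the three
    sum to 100.  ``illness_then_death`` is the share of illness subjects
    later observed to die.
    """
    first = episodes[episodes["from"] == 1]
    nsub = len(first)
    to = first["to"].to_numpy()
    ill_ids = set(first.loc[first["to"] == 2, "id"])
    died_after = episodes[(episodes["from"] == 2) & (episodes["to"] == 3)]
    return {
        "censored": 100.0 * (to == 0).mean(),
        "illness": 100.0 * (to == 2).mean(),
        "direct_death": 100.0 * (to == 3).mean(),
        "illness_then_death": 100.0 * len(died_after) / max(len(ill_ids), 1),
        "n_subjects": nsub,
    }


def state1_at_risk_fraction(config: SimConfig, s: float = 0.5, seed=None,
                            n_subjects: int = 100_000,
                            denominator: str = "state1_entrants") -> float:
    """Percentage of individuals under observation and healthy at time ``s``.

    The numerator counts subjects whose truncation time precedes ``s``,
    who are uncensored at ``s`` and still in state 1 at ``s`` (the
    landmark risk set at origin ``s``).  The ``denominator`` is either
    ``"state1_entrants"`` — subjects ever under observation in state 1,
    i.e. the pool a landmark analysis at origin ``(1, s)`` draws on — or
    ``"all"`` — every simulated subject, including those never observed
    because truncation outlasts their censoring or event time.  Simulated
    on a large reference cohort under ``config``.
    """
    rng = np.random.default_rng(seed)
    a, b = config.size_range
    n_cl = int(np.ceil(n_subjects / ((a + b) / 2)))
    lat = _simulate_latent(config, rng, n_clusters=n_cl)
    ok = (lat["L"] < s) & (lat["C"] > s) & (lat["T1"] > s)
    if denominator == "state1_entrants":
        pool = (lat["L"] < lat["T1"]) & (lat["L"] < lat["C"])
        return 100.0 * ok[pool].mean()
    if denominator == "all":
        return 100.0 * ok.mean()
    raise ValueError("denominator must be 'state1_entrants' or 'all'")


# ---------------------------------------------------------------------------
# closed-form population-averaged truths (gamma(1,1) frailty)

def _size_weights(config: SimConfig, population: str):
    a, b = config.size_range
    m = np.arange(a, b + 1)
    p = np.full(len(m), 1.0 / len(m))
    if population == "acm":
        w = p * m / (p * m).sum()
    else:
        w = p
    return m, w


def _slope12(config: SimConfig, m, arm) -> np.ndarray:
    s12 = config.slope_12 + config.ics_bump * (m <= config.expected_size)
    if arm == 2:
        s12 = s12 + config.arm_effect
    return s12


def _p2_conditional(s12, s13, s23, t):
    """Marginal (over gamma frailty) P(X(t) = 2) given cluster size."""
    t = np.asarray(t, dtype=float)
    aa = s12 + s13
    if abs(aa - s23) > 1e-12:
        return (s12 / (aa - s23)) * (1.0 / (1.0 + s23 * t) - 1.0 / (1.0 + aa * t))
    return s12 * t / (1.0 + aa * t) ** 2


def true_occupation(config: SimConfig, times, population: str = "acm",
                    state: int = 2, arm: Optional[int] = None) -> np.ndarray:
    """Closed-form population-averaged occupation probability ``P_j(t)``.

    The conditional constant-hazard illness-death solution is integrated
    against the gamma frailty analytically (``E exp(-c v t) = 1/(1+ct)``)
    and mixed over cluster sizes with weights ``p(m) m / E M`` (ACM) or
    ``p(m)`` (TCM).
    """
    times = np.asarray(times, dtype=float)
    m, w = _size_weights(config, population)
    s13, s23 = config.slope_13, config.slope_23
    p1 = np.zeros_like(times)
    p2 = np.zeros_like(times)
    for mm, ww in zip(m, w):
        s12 = _slope12(config, np.array([mm]), arm)[0]
        aa = s12 + s13
        p1 += ww / (1.0 + aa * times)
        p2 += ww * _p2_conditional(s12, s13, s23, times)
    if state == 1:
        return p1
    if state == 2:
        return p2
    return 1.0 - p1 - p2


def true_transition_12(config: SimConfig, s: float, times,
                       population: str = "acm", arm: Optional[int] = None) -> np.ndarray:
    """Closed-form population-averaged ``P_12(s, t)``.

    The partly conditional target ``E[w 1(X(t)=2, X(s)=1)] / E[w 1(X(s)=1)]``
    with ``w`` the population weight; both expectations have closed forms
    under the gamma frailty.
    """
    times = np.asarray(times, dtype=float)
    m, w = _size_weights(config, population)
    s13, s23 = config.slope_13, config.slope_23
    num = np.zeros_like(times)
    den = 0.0
    for mm, ww in zip(m, w):
        s12 = _slope12(config, np.array([mm]), arm)[0]
        aa = s12 + s13
        diff = aa - s23
        if abs(diff) > 1e-12:
            nm = (s12 / diff) * (
                1.0 / (1.0 + s23 * times + diff * s) - 1.0 / (1.0 + aa * times)
            )
        else:
            nm = s12 * (times - s) / (1.0 + aa * times) ** 2
        num += ww * np.where(times >= s, nm, 0.0)
        den += ww / (1.0 + aa * s)
    return num / den


def true_probability(config: SimConfig, kind: str, times, population: str = "acm",
                     state: int = 2, s: float = 0.0, arm: Optional[int] = None):
    """Dispatch to the closed-form occupation or transition truth."""
    if kind == "occupation":
        return true_occupation(config, times, population, state, arm)
    if kind == "transition":
        return true_transition_12(config, s, times, population, arm)
    raise ValueError("kind must be 'occupation' or 'transition'")


def followup_percentile(config: SimConfig, q: float, n_subjects: int = 1_000_000,
                        seed: int = 20_200_721) -> float:
    """Population ``q``-th percentile of the observed follow-up duration.

    Follow-up is the time from study entry to exit from observation
    (absorption or censoring, whichever comes first).  A large reference
    cohort with a fixed internal seed is used, so the returned time is a
    deterministic function of the configuration and common across
    replicates of an experiment.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    a, b = config.size_range
    n_cl = int(np.ceil(n_subjects / ((a + b) / 2)))
    lat = _simulate_latent(config, rng, n_clusters=n_cl)
    end = np.minimum(lat["death"], lat["C"])
    observed = lat["L"] < end
    fu = end[observed] - lat["L"][observed]
    return float(np.quantile(fu, q))
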