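"""Markov gating model of a voltage-gated sodium channel with drug binding.

The channel is a continuous-time Markov chain over a small set of gating
states (default C1, C2, O, I).  A bound inhibitor doubles the state space:
every gating state X has an unbound copy X and a bound copy X*.  Binding obeys
a two-affinity (modulated-receptor) scheme: states are partitioned into a
resting class (dissociation constant ``K_R``) and an inactivated class
(``K_I``), with a single association rate ``k_on`` optionally attenuated per
state by guarded-receptor access factors.  Gating rates in the bound layer are
rescaled so that every unbound/bound thermodynamic 4-cycle satisfies
microscopic reversibility (see :func:`build_rate_matrix`).

Rates follow a single-exponential voltage dependence ``r(V) = A·exp(V/k_V)``;
``k_V = inf`` gives a voltage-independent rate.  Units: ms, mV, µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RateLaw",
    "ChannelModel",
    "CompoundMechanism",
    "generic_fast_nav",
    "build_rate_matrix",
    "propagate",
    "occupancy_course",
    "equilibrium_occupancy",
    "bound_escape_tau_ms",
]


@dataclass(frozen=True)
class RateLaw:
    """Voltage-dependent transition rate ``r(V) = A * exp(V / k_V)``.

    ``A`` in 1/ms, ``k_V`` in mV; ``k_V = +/-inf`` (or ``None``) makes the
    rate voltage independent.
    """

    A: float
    k_V: Optional[float] = None

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"rate amplitude must be >= 0, got {self.A}")

    def __call__(self, V: float) -> float:
        if self.k_V is None or math.isinf(self.k_V):
            return self.A
        return self.A * math.exp(V / self.k_V)


@dataclass
class ChannelModel:
    """Gating topology, rate laws and conductance of the drug-free channel."""

    states: tuple[str, ...]
    rate_laws: dict[tuple[str, str], RateLaw]
    open_states: tuple[str, ...] = ("O",)
    inactivated_states: tuple[str, ...] = ("I",)
    conductance_scale_nA: float = 10.0

    def __post_init__(self) -> None:
        for (a, b) in self.rate_laws:
            if a not in self.states or b not in self.states:
                raise ValueError(f"rate law references unknown state: {(a, b)}")
            if a == b:
                raise ValueError("self-transitions are not allowed")
        for s in self.open_states + self.inactivated_states:
            if s not in self.states:
                raise ValueError(f"unknown state {s!r}")
        # connectivity of the undirected gating graph
        adj = {s: set() for s in self.states}
        for (a, b) in self.rate_laws:
            adj[a].add(b)
            adj[b].add(a)
        seen, stack = set(), [self.states[0]]
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            seen.add(s)
            stack.extend(adj[s] - seen)
        if seen != set(self.states):
            raise ValueError("gating graph is not connected")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    def gating_generator(self, V: float) -> np.ndarray:
        """Generator matrix of the drug-free gating chain at voltage ``V``."""
        n = self.n_states
        Q = np.zeros((n, n))
        for (a, b), law in self.rate_laws.items():
            r = law(V)
            if r < 0:
                raise ValueError(f"negative rate for {(a, b)} at V={V}")
            i, j = self.state_index(a), self.state_index(b)
            Q[i, j] += r
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q


def generic_fast_nav(conductance_scale_nA: float = 10.0) -> ChannelModel:
    """Generic fast Na_V gating model (C1 <-> C2 <-> O <-> I plus I <-> C1).

    Engineering defaults chosen so that activation and inactivation are
    complete within ~5 ms at -10 mV, recovery from inactivation has a time
    constant of a few ms at -130 mV, roughly half the population is
    inactivated at steady state at -70 mV, and resting inactivation at
    -130 mV is negligible (< 0.1%, so that the rested-pulse IC50 is an
    essentially uncontaminated probe of the resting-state affinity).  They
    are not fitted to any particular recorded channel.
    """
    return ChannelModel(
        states=("C1", "C2", "O", "I"),
        rate_laws={
            ("C1", "C2"): RateLaw(8.0, 36.0),
            ("C2", "C1"): RateLaw(0.4, -36.0),
            ("C2", "O"): RateLaw(8.0, 36.0),
            ("O", "C2"): RateLaw(0.4, -36.0),
            ("O", "I"): RateLaw(1.5, None),
            ("I", "O"): RateLaw(1e-4, 30.0),
            ("I", "C1"): RateLaw(0.067, -87.0),
        },
        open_states=("O",),
        inactivated_states=("I",),
        conductance_scale_nA=conductance_scale_nA,
    )


@dataclass
class CompoundMechanism:
    """Ground-truth binding mechanism of a simulated inhibitor.

    Parameters
    ----------
    k_on : association rate constant, 1/(µM·ms).
    K_R, K_I : resting- and inactivated-state dissociation constants, µM.
        Unbinding rates are ``k_on*K_R`` from resting-class states and
        ``k_on*K_I`` from inactivated-class states.
    access_factors : per-state multiplier on ``k_on`` in (0, 1]
        (guarded-receptor accessibility).  Missing states default to 1.
    perfusion_tau_s : exponential wash-in/wash-out time constant, seconds.
    closure : where the K_R/K_I thermodynamic factor is placed in the bound
        layer.  ``"recovery"`` (default) divides bound-layer rates going from
        an inactivated-class to a resting-class state by K_R/K_I (bound
        channels recover from inactivation more slowly, reproducing the
        drug-induced delay of recovery).  ``"onset"`` multiplies the forward
        rates instead (bound channels inactivate faster); note that this
        makes open-state binding an almost irreversible sink for strongly
        state-dependent compounds.
    bound_open_conductance : relative conductance of bound open states
        (0 = pure block).
    """

    name: str = "compound"
    k_on: float = 1e-3
    K_R: float = 100.0
    K_I: float = 10.0
    access_factors: dict[str, float] = field(default_factory=dict)
    perfusion_tau_s: float = 2.0
    closure: str = "recovery"
    bound_open_conductance: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.K_R <= 0 or self.K_I <= 0:
            raise ValueError("K_R and K_I must be > 0")
        if self.closure not in ("onset", "recovery"):
            raise ValueError(f"unknown closure {self.closure!r}")
        for s, f in self.access_factors.items():
            if not (0 <= f <= 1):
                raise ValueError(f"access factor for {s} must be in [0, 1]")
        if self.perfusion_tau_s <= 0:
            raise ValueError("perfusion_tau_s must be > 0")

    def K_of(self, channel: ChannelModel, state: str) -> float:
        return self.K_I if state in channel.inactivated_states else self.K_R

    def access_of(self, state: str) -> float:
        return self.access_factors.get(state, 1.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompoundMechanism":
        return cls(**dict(d))


def build_rate_matrix(
    channel: ChannelModel,
    drug: CompoundMechanism,
    V: float,
    conc: float,
) -> np.ndarray:
    """Generator over {gating states} x {unbound, bound} at fixed V and conc.

    State order: the channel's gating states first (unbound), then their
    bound copies.  Binding from state X uses rate ``access(X)*k_on*conc``;
    unbinding uses ``k_on*K_R`` (resting class) or ``k_on*K_I`` (inactivated
    class).  Bound-layer gating rates are rescaled so that every
    unbound<->bound 4-cycle X -> Y -> Y* -> X* -> X has equal clockwise and
    counterclockwise rate products.  Writing ``w(X) = K(X)/access(X)``, the
    bound rate X* -> Y* is the unbound rate times ``max(w(X)/w(Y), 1)``
    ("onset" closure) or ``min(w(X)/w(Y), 1)`` ("recovery" closure).
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    n = channel.n_states
    Q = np.zeros((2 * n, 2 * n))

    def w(state: str) -> float:
        af = drug.access_of(state)
        if af == 0:
            raise ValueError(
                f"cycle closure undefined with zero access factor for state "
                f"{state!r}; use the affinity class instead"
            )
        return drug.K_of(channel, state) / af

    for (a, b), law in channel.rate_laws.items():
        r = law(V)
        i, j = channel.state_index(a), channel.state_index(b)
        Q[i, j] += r  # unbound layer: plain gating
        ratio = w(a) / w(b)
        scale = max(ratio, 1.0) if drug.closure == "onset" else min(ratio, 1.0)
        Q[n + i, n + j] += r * scale

    for s in channel.states:
        i = channel.state_index(s)
        Q[i, n + i] += drug.access_of(s) * drug.k_on * conc
        Q[n + i, i] += drug.k_on * drug.K_of(channel, s)

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _check_occupancy(occ: np.ndarray) -> np.ndarray:
    occ = np.asarray(occ, dtype=float)
    if occ.ndim != 1:
        raise ValueError("occupancy must be a 1-D vector")
    if occ.min() < -1e-10 or abs(occ.sum() - 1.0) > 1e-8:
        raise ValueError("occupancy must be a probability vector")
    return np.clip(occ, 0.0, None)


def propagate(occ: np.ndarray, Q: np.ndarray, duration_ms: float) -> np.ndarray:
    """Evolve an occupancy vector for ``duration_ms`` under a constant generator.

    Row-vector convention: ``occ(t) = occ(0) @ expm(Q t)``.
    """
    occ = _check_occupancy(occ)
    if duration_ms < 0:
        raise ValueError("duration must be >= 0")
    if duration_ms == 0:
        return occ.copy()
    out = occ @ expm(Q * duration_ms)
    out = np.clip(out, 0.0, None)
    s = out.sum()
    if abs(s - 1.0) > 1e-9:
        out = out / s
    return out


def occupancy_course(
    occ: np.ndarray, Q: np.ndarray, duration_ms: float, dt_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy sampled on a fine grid within one constant-voltage segment.

    Returns ``(times, occ_t)`` with ``occ_t`` of shape (n_times, n_states),
    including both endpoints.  Uses an eigendecomposition of the generator
    when it is well conditioned, otherwise repeated one-step propagation.
    """
    occ = _check_occupancy(occ)
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    n_steps = max(1, int(round(duration_ms / dt_ms)))
    ts = np.linspace(0.0, duration_ms, n_steps + 1)
    try:
        lam, Vr = np.linalg.eig(Q.T)
        cond = np.linalg.cond(Vr)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned eigenvector matrix")
        c = np.linalg.solve(Vr, occ)
        course = np.real(np.einsum("ik,kt->ti", Vr, c[:, None] * np.exp(np.outer(lam, ts))))
    except np.linalg.LinAlgError:
        P = expm(Q * (ts[1] - ts[0]))
        course = np.empty((len(ts), len(occ)))
        course[0] = occ
        for k in range(1, len(ts)):
            course[k] = course[k - 1] @ P
    course = np.clip(course, 0.0, None)
    course /= course.sum(axis=1, keepdims=True)
    return ts, course


def bound_escape_tau_ms(
    channel: ChannelModel,
    drug: CompoundMechanism,
    V: float = -130.0,
    conc: float = 0.0,
    t_max_ms: float = 5000.0,
) -> float:
    """Effective escape time constant of bound drug at a holding potential.

    Starts with the whole population in the bound inactivated state(s) (the
    state bound drug accumulates in during depolarization) and returns the
    time at which the excess bound occupancy over its stationary value has
    decayed by a factor e.  At ``conc = 0`` this is the micro-offset
    timescale set by unbinding and bound-state recovery; at positive bath
    concentration it includes rebinding of not-yet-recovered channels, which
    prolongs the observable offset.
    """
    n = channel.n_states
    occ0 = np.zeros(2 * n)
    idx = [n + channel.state_index(s) for s in channel.inactivated_states]
    occ0[idx] = 1.0 / len(idx)
    Q = build_rate_matrix(channel, drug, V, conc)
    b_eq = float(equilibrium_occupancy(Q)[n:].sum())
    ts, course = occupancy_course(occ0, Q, t_max_ms, t_max_ms / 20000.0)
    excess = course[:, n:].sum(axis=1) - b_eq
    e0 = excess[0]
    if e0 <= 0:
        raise ValueError("initial bound occupancy does not exceed equilibrium")
    target = e0 / np.e
    below = np.nonzero(excess <= target)[0]
    if len(below) == 0:
        raise ValueError(f"bound occupancy did not relax within {t_max_ms} ms")
    k = below[0]
    if k == 0:
        return float(ts[0])
    f = (excess[k - 1] - target) / (excess[k - 1] - excess[k])
    return float(ts[k - 1] + f * (ts[k] - ts[k - 1]))


def equilibrium_occupancy(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (left null vector of Q)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    occ, *_ = np.linalg.lstsq(A, b, rcond=None)
    occ = np.clip(occ, 0.0, None)
    return occ / occ.sum()
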