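"""Whole-cell current simulation under step protocols with drug perfusion.

A sweep is simulated by chaining the occupancy vector through the protocol's
constant-voltage segments (matrix-exponential propagation).  Peak currents are
read out on a fine time grid inside each test pulse; by default only unbound
open channels conduct (pure open-channel block), so

    I(t) = -conductance_scale * [P_open_unbound(t) + g_b * P_open_bound(t)]

with ``g_b`` the relative bound-open conductance (0 by default).  Inward
current is negative.

An experiment is a train of sweeps at one per ``sweep_period``; the applied
concentration follows the perfusion schedule, relaxing exponentially toward
each block's target with the compound's ``perfusion_tau_s``.  Measurement
noise is multiplicative Gaussian on the per-pulse peaks, with an optional
linear rundown; all randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .channel import (
    ChannelModel,
    CompoundMechanism,
    build_rate_matrix,
    equilibrium_occupancy,
    occupancy_course,
)
from .protocol import ROLE_TEST_PULSE, VoltageProtocol

__all__ = [
    "NoiseModel",
    "SweepResult",
    "SimulatedExperiment",
    "simulate_sweep",
    "perfusion_concentrations",
    "simulate_experiment",
    "apply_noise",
    "AMPLITUDE_COLUMNS",
]

AMPLITUDE_COLUMNS = ["sweep_index", "time_s", "pulse_index", "amplitude_nA", "conc_uM"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model applied to per-pulse peak amplitudes."""

    multiplicative_sd: float = 0.02
    rundown_per_sweep: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0:
            raise ValueError("multiplicative_sd must be >= 0")
        if self.rundown_per_sweep < 0:
            raise ValueError("rundown_per_sweep must be >= 0")


@dataclass
class SweepResult:
    peaks_nA: dict[int, float]
    occ_final: np.ndarray
    trace_time_ms: Optional[np.ndarray] = None
    trace_current_nA: Optional[np.ndarray] = None
    segment_end_occupancies: Optional[list[np.ndarray]] = None


class _QCache:
    """Per-run cache of generators and step propagators."""

    def __init__(self, channel: ChannelModel, drug: Optional[CompoundMechanism]):
        self.channel = channel
        self.drug = drug
        self._Q: dict[tuple[float, float], np.ndarray] = {}
        self._P: dict[tuple[float, float, float], np.ndarray] = {}

    def Q(self, V: float, conc: float) -> np.ndarray:
        key = (V, conc)
        if key not in self._Q:
            if self.drug is None:
                self._Q[key] = self.channel.gating_generator(V)
            else:
                self._Q[key] = build_rate_matrix(self.channel, self.drug, V, conc)
        return self._Q[key]

    def P(self, V: float, conc: float, dur_ms: float) -> np.ndarray:
        key = (V, conc, dur_ms)
        if key not in self._P:
            self._P[key] = expm(self.Q(V, conc) * dur_ms)
        return self._P[key]


def _open_weights(channel: ChannelModel, drug: Optional[CompoundMechanism]) -> np.ndarray:
    n = channel.n_states
    m = n if drug is None else 2 * n
    wt = np.zeros(m)
    for s in channel.open_states:
        i = channel.state_index(s)
        wt[i] = 1.0
        if drug is not None:
            wt[n + i] = drug.bound_open_conductance
    return wt


def resting_occupancy(
    channel: ChannelModel,
    drug: Optional[CompoundMechanism],
    V: float,
    conc: float = 0.0,
) -> np.ndarray:
    """Stationary occupancy at a holding potential (and bath concentration)."""
    if drug is None:
        return equilibrium_occupancy(channel.gating_generator(V))
    return equilibrium_occupancy(build_rate_matrix(channel, drug, V, conc))


def simulate_sweep(
    channel: ChannelModel,
    drug: Optional[CompoundMechanism],
    protocol: VoltageProtocol,
    conc: float = 0.0,
    occ0: Optional[np.ndarray] = None,
    peak_dt_ms: float = 0.01,
    return_trace: bool = False,
    trace_dt_ms: float = 0.05,
    record_states: bool = False,
    _cache: Optional[_QCache] = None,
) -> SweepResult:
    """Simulate one sweep; return per-pulse peak currents and final occupancy.

    ``occ0`` defaults to the bath equilibrium at the terminal (pre-pulse)
    holding voltage, i.e. the last segment's voltage, since sweeps repeat
    cyclically.  Peaks are signed (inward negative).  The implicit remainder of
    the sweep period (if segment durations sum to less than the period) is
    spent at the last segment's voltage.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if protocol.n_pulses == 0:
        raise ValueError("protocol has no test pulses")
    cache = _cache or _QCache(channel, drug)
    wt = _open_weights(channel, drug)
    if occ0 is None:
        occ = resting_occupancy(channel, drug, protocol.segments[-1].voltage_mV, conc)
    else:
        occ = np.asarray(occ0, dtype=float)
        if occ.shape != wt.shape:
            raise ValueError(
                f"occupancy has {occ.shape[0]} entries, model has {wt.shape[0]} states"
            )

    peaks: dict[int, float] = {}
    seg_end_occ: list[np.ndarray] = []
    times_parts: list[np.ndarray] = []
    current_parts: list[np.ndarray] = []
    t_cursor = 0.0

    remainder = protocol.sweep_period_ms - protocol.total_segment_ms()
    segments = list(protocol.segments)
    extra = None
    if remainder > 1e-9:
        extra = (remainder, segments[-1].voltage_mV)

    for seg in segments:
        Q = cache.Q(seg.voltage_mV, conc)
        need_course = seg.role == ROLE_TEST_PULSE or return_trace
        if need_course:
            dt = peak_dt_ms if seg.role == ROLE_TEST_PULSE else trace_dt_ms
            ts, course = occupancy_course(occ, Q, seg.duration_ms, dt)
            open_p = course @ wt
            if seg.role == ROLE_TEST_PULSE:
                # peak relative to the instantaneous pre-pulse current level
                # (window current at depolarized holdings subtracts out, the
                # same convention the trace-processing baseline uses)
                peaks[seg.pulse_index] = -channel.conductance_scale_nA * float(
                    open_p.max() - open_p[0]
                )
            if return_trace:
                # sample on the trace grid (test pulses were computed on the
                # finer peak grid; subsample to keep the output uniform)
                stride = max(1, int(round(trace_dt_ms / dt)))
                times_parts.append(t_cursor + ts[:-1:stride])
                current_parts.append(-channel.conductance_scale_nA * open_p[:-1:stride])
            occ = course[-1]
        else:
            occ = np.clip(occ @ cache.P(seg.voltage_mV, conc, seg.duration_ms), 0.0, None)
            occ /= occ.sum()
        if record_states:
            seg_end_occ.append(occ.copy())
        t_cursor += seg.duration_ms

    if extra is not None:
        dur, V = extra
        if return_trace:
            ts, course = occupancy_course(occ, cache.Q(V, conc), dur, trace_dt_ms)
            times_parts.append(t_cursor + ts[:-1])
            current_parts.append(-channel.conductance_scale_nA * (course @ wt)[:-1])
            occ = course[-1]
        else:
            occ = np.clip(occ @ cache.P(V, conc, dur), 0.0, None)
            occ /= occ.sum()

    result = SweepResult(peaks_nA=peaks, occ_final=occ)
    if return_trace:
        result.trace_time_ms = np.concatenate(times_parts)
        result.trace_current_nA = np.concatenate(current_parts)
    if record_states:
        result.segment_end_occupancies = seg_end_occ
    return result


def perfusion_concentrations(
    schedule: Sequence[tuple[int, float]],
    tau_s: float,
    sweep_period_s: float = 1.0,
    c0: float = 0.0,
) -> np.ndarray:
    """Applied concentration at the start of each sweep.

    ``schedule`` is a sequence of ``(n_sweeps, target_conc_uM)`` blocks; the
    bath concentration relaxes exponentially toward each block's target with
    time constant ``tau_s``.
    """
    if len(schedule) == 0:
        raise ValueError("perfusion schedule is empty")
    decay = np.exp(-sweep_period_s / tau_s)
    out = []
    c = c0
    for n_sweeps, target in schedule:
        if n_sweeps <= 0:
            raise ValueError("schedule block must cover >= 1 sweep")
        if target < 0:
            raise ValueError("negative target concentration")
        for _ in range(int(n_sweeps)):
            out.append(c)
            c = target + (c - target) * decay
    return np.array(out)


@dataclass
class SimulatedExperiment:
    """Per-sweep x per-pulse peak amplitudes from one simulated recording."""

    amplitudes: pd.DataFrame          # AMPLITUDE_COLUMNS, noise applied
    noiseless: pd.DataFrame           # same rows without noise
    schedule: tuple[tuple[int, float], ...]
    seed: Optional[int]
    noise: NoiseModel
    channel: ChannelModel
    drug: Optional[CompoundMechanism]
    protocol: VoltageProtocol
    occupancies: Optional[list[list[np.ndarray]]] = None

    def with_noise(self, seed: int, noise: Optional[NoiseModel] = None) -> pd.DataFrame:
        """Re-draw measurement noise on the same underlying peaks."""
        return apply_noise(self.noiseless, noise or self.noise, seed)

    def ground_truth(self) -> dict:
        gt = {
            "schedule": [list(b) for b in self.schedule],
            "seed": self.seed,
            "noise": {
                "multiplicative_sd": self.noise.multiplicative_sd,
                "rundown_per_sweep": self.noise.rundown_per_sweep,
            },
            "sweep_period_ms": self.protocol.sweep_period_ms,
        }
        if self.drug is not None:
            gt["mechanism"] = self.drug.to_dict()
        return gt


def apply_noise(
    noiseless: pd.DataFrame, noise: NoiseModel, seed: int
) -> pd.DataFrame:
    """Multiplicative Gaussian noise + optional linear rundown on peaks."""
    rng = np.random.default_rng(seed)
    df = noiseless.copy()
    factors = 1.0 + noise.multiplicative_sd * rng.standard_normal(len(df))
    if noise.rundown_per_sweep > 0:
        factors *= 1.0 - noise.rundown_per_sweep * df["sweep_index"].to_numpy()
    df["amplitude_nA"] = df["amplitude_nA"].to_numpy() * factors
    return df


def simulate_experiment(
    channel: ChannelModel,
    drug: Optional[CompoundMechanism],
    protocol: VoltageProtocol,
    schedule: Sequence[tuple[int, float]],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    peak_dt_ms: float = 0.01,
    record_states: bool = False,
) -> SimulatedExperiment:
    """Simulate a full perfusion experiment (one sweep per sweep period).

    Occupancy is chained across sweeps; identical seed gives identical output.
    """
    schedule = tuple((int(n), float(c)) for n, c in schedule)
    tau = drug.perfusion_tau_s if drug is not None else 1.0
    sweep_period_s = protocol.sweep_period_ms / 1000.0
    concs = perfusion_concentrations(schedule, tau, sweep_period_s)

    cache = _QCache(channel, drug)
    occ = resting_occupancy(channel, drug, protocol.segments[-1].voltage_mV, concs[0])
    rows = []
    occ_records: list[list[np.ndarray]] = []
    for sweep_i, conc in enumerate(concs):
        res = simulate_sweep(
            channel, drug, protocol, conc=float(conc), occ0=occ,
            peak_dt_ms=peak_dt_ms, record_states=record_states, _cache=cache,
        )
        occ = res.occ_final
        t_s = sweep_i * sweep_period_s
        for p, amp in sorted(res.peaks_nA.items()):
            rows.append((sweep_i, t_s, p, amp, conc))
        if record_states:
            occ_records.append(res.segment_end_occupancies)

    noiseless = pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS)
    noisy = apply_noise(noiseless, noise, seed) if noise.multiplicative_sd > 0 or \
        noise.rundown_per_sweep > 0 else noiseless.copy()
    return SimulatedExperiment(
        amplitudes=noisy,
        noiseless=noiseless,
        schedule=schedule,
        seed=seed,
        noise=noise,
        channel=channel,
        drug=drug,
        protocol=protocol,
        occupancies=occ_records if record_states else None,
    )
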