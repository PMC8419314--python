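"""Raw-sweep processing: peak extraction, leak subtraction, phase annotation.

Sign convention: inward sodium current is negative; all downstream ratio
computations use absolute amplitudes.  The per-pulse peak is the most
negative sample in the pulse window after capacitive-artifact blanking and
(optionally) subtraction of a linear leak estimated from the pre-pulse
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .protocol import ROLE_CONDITIONING, ROLE_TEST_PULSE, VoltageProtocol

__all__ = [
    "SweepTrace",
    "extract_peaks",
    "annotate_phases",
    "peaks_to_amplitude_rows",
]


@dataclass
class SweepTrace:
    """One digitized sweep (uniform sampling, default 20 kHz)."""

    time_ms: np.ndarray
    current_nA: np.ndarray
    sweep_index: int = 0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if self.time_ms.shape != self.current_nA.shape:
            raise ValueError("time and current arrays differ in length")
        if len(self.time_ms) < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace sampling must be uniform")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


def _depolarized_windows(protocol: VoltageProtocol) -> list[tuple[float, float]]:
    """Windows occupied by test pulses or conditioning depolarizations."""
    wins, t = [], 0.0
    for seg in protocol.segments:
        if seg.role in (ROLE_TEST_PULSE, ROLE_CONDITIONING):
            wins.append((t, t + seg.duration_ms))
        t += seg.duration_ms
    return wins


def _step_times(protocol: VoltageProtocol) -> np.ndarray:
    """Times of command-voltage steps (segment boundaries with a V change)."""
    steps, t, v_prev = [], 0.0, None
    for seg in protocol.segments:
        if v_prev is None or seg.voltage_mV != v_prev:
            steps.append(t)
        v_prev = seg.voltage_mV
        t += seg.duration_ms
    steps.append(t)
    return np.asarray(steps)


def extract_peaks(
    trace: SweepTrace,
    protocol: VoltageProtocol,
    blank_ms: float = 0.2,
    leak_mode: str = "baseline_linear",
    baseline_ms: float = 10.0,
) -> np.ndarray:
    """Signed peak current of every test pulse in one sweep.

    For each test pulse the search window is ``[start + blank_ms, end)``.
    With ``leak_mode="baseline_linear"`` a straight line is fitted to the
    quiet pre-pulse baseline (samples within ``baseline_ms`` before the pulse
    that are outside depolarized segments and at least ``blank_ms`` past any
    command step) and subtracted before taking the extremum.

    Returns an array of peaks ordered by pulse index.
    """
    if blank_ms < 0:
        raise ValueError("blank_ms must be >= 0")
    if leak_mode not in ("baseline_linear", "none"):
        raise ValueError(f"unknown leak_mode {leak_mode!r}")

    windows = protocol.test_pulse_windows()
    t = trace.time_ms
    i_raw = trace.current_nA
    depol = _depolarized_windows(protocol)
    steps = _step_times(protocol)

    quiet = np.ones(len(t), dtype=bool)
    for (a, b) in depol:
        quiet &= ~((t >= a - 1e-9) & (t < b - 1e-9))
    for s in steps:
        quiet &= ~((t >= s - 1e-9) & (t < s + blank_ms - 1e-9))

    peaks = np.empty(len(windows))
    for k, idx in enumerate(sorted(windows)):
        start, end = windows[idx]
        if blank_ms >= (end - start):
            raise ValueError(
                f"blanking window ({blank_ms} ms) covers the whole of pulse #{idx}"
            )
        sel = (t >= start + blank_ms - 1e-9) & (t < end - 1e-9)
        if not sel.any():
            raise ValueError(f"no samples inside the window of pulse #{idx}")
        y = i_raw[sel]
        if leak_mode == "baseline_linear":
            base = quiet & (t >= start - baseline_ms) & (t < start)
            look_back = baseline_ms
            while base.sum() < 2 and look_back < protocol.total_segment_ms():
                look_back *= 2
                base = quiet & (t >= start - look_back) & (t < start)
            if base.sum() < 2:
                # a pulse at the sweep start has no preceding baseline; use
                # the quiet window right after it instead (a linear leak
                # extrapolates backwards just as well)
                base = quiet & (t >= end) & (t < end + baseline_ms)
            if base.sum() < 2:
                raise ValueError(
                    f"not enough baseline samples around pulse #{idx} for "
                    "leak fit"
                )
            slope, offset = np.polyfit(t[base], i_raw[base], 1)
            y = y - (slope * t[sel] + offset)
        peaks[k] = y.min()
    return peaks


def peaks_to_amplitude_rows(
    peaks: np.ndarray,
    protocol: VoltageProtocol,
    sweep_index: int,
    time_s: float,
    conc_uM: float = 0.0,
) -> pd.DataFrame:
    """Arrange one sweep's peak vector as amplitude-table rows."""
    idx = sorted(protocol.test_pulse_windows())
    return pd.DataFrame(
        {
            "sweep_index": sweep_index,
            "time_s": time_s,
            "pulse_index": idx,
            "amplitude_nA": peaks,
            "conc_uM": conc_uM,
        }
    )


def annotate_phases(
    amplitudes: pd.DataFrame,
    schedule: Sequence[tuple[int, float]],
    control_window_s: float = 5.0,
    drug_window_s: float = 5.0,
    sweep_period_s: float = 1.0,
) -> pd.DataFrame:
    """Tag analysis sweeps: per-application controls and end-of-application drug.

    ``schedule`` is the perfusion schedule as ``(n_sweeps, target_conc_uM)``
    blocks.  For each application (block with positive target), the last
    ``drug_window_s`` of the block is tagged ``drug_k`` and the last
    ``control_window_s`` of the immediately preceding drug-free stretch is
    tagged ``control_k`` (each application gets its own control set).  Adds
    columns ``phase`` (empty string where untagged), ``application`` (0 where
    untagged) and ``conc_applied_uM`` (the application's target).
    """
    if len(schedule) == 0:
        raise ValueError("perfusion schedule is empty")
    if control_window_s <= 0 or drug_window_s <= 0:
        raise ValueError("windows must be > 0")
    schedule = [(int(n), float(c)) for n, c in schedule]
    n_sched = sum(n for n, _ in schedule)
    sweeps = np.sort(amplitudes["sweep_index"].unique())
    if len(sweeps) != n_sched or sweeps[0] != 0 or sweeps[-1] != n_sched - 1:
        raise ValueError(
            f"schedule covers {n_sched} sweeps but the amplitude table has "
            f"sweeps {sweeps[0]}..{sweeps[-1]} ({len(sweeps)} distinct)"
        )
    n_control = max(1, int(round(control_window_s / sweep_period_s)))
    n_drug = max(1, int(round(drug_window_s / sweep_period_s)))

    phase = {}
    application = {}
    conc_applied = {}
    start = 0
    app_k = 0
    block_bounds = []
    for n, c in schedule:
        block_bounds.append((start, start + n, c))
        start += n
    for bi, (b0, b1, c) in enumerate(block_bounds):
        if c <= 0:
            continue
        app_k += 1
        if b1 - b0 <= n_drug:
            raise ValueError(
                f"application {app_k} ({b1 - b0} sweeps) is not longer than "
                f"the {n_drug}-sweep drug window"
            )
        for s in range(b1 - n_drug, b1):
            phase[s] = f"drug_{app_k}"
            application[s] = app_k
            conc_applied[s] = c
        # preceding drug-free stretch
        if bi == 0 or block_bounds[bi - 1][2] > 0:
            raise ValueError(
                f"application {app_k} has no preceding drug-free control block"
            )
        c0, c1, _ = block_bounds[bi - 1]
        if c1 - c0 < n_control:
            raise ValueError(
                f"control block before application {app_k} is shorter than "
                f"the {n_control}-sweep control window"
            )
        for s in range(c1 - n_control, c1):
            phase[s] = f"control_{app_k}"
            application[s] = app_k
            conc_applied[s] = c
    if app_k == 0:
        raise ValueError("schedule contains no drug application")

    out = amplitudes.copy()
    si = out["sweep_index"]
    out["phase"] = si.map(phase).fillna("")
    out["application"] = si.map(application).fillna(0).astype(int)
    out["conc_applied_uM"] = si.map(conc_applied).fillna(0.0)
    return out
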