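"""Piecewise-constant voltage-clamp protocols and the 17-pulse SDO/RFI/SSI protocol.

The central object is :class:`VoltageProtocol`: an ordered list of
constant-voltage segments, repeated once per ``sweep_period_ms``, with 17
labelled test pulses.  Three sections of the protocol probe different aspects
of state-dependent inhibition:

* **SDO** (state-dependent onset): test pulses preceded by depolarizing
  conditioning prepulses of increasing duration.
* **RFI** (recovery from inactivation): test pulses preceded by
  hyperpolarizing gaps of increasing duration.
* **SSI** (steady-state inactivation): test pulses fired from holding levels
  of increasing (less negative) potential.

Durations are milliseconds, voltages millivolts.  Segment boundaries are
half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ROLE_TEST_PULSE",
    "ROLE_CONDITIONING",
    "ROLE_GAP",
    "ROLE_HOLDING",
    "SECTION_SDO",
    "SECTION_RFI",
    "SECTION_SSI",
    "VoltageSegment",
    "PulseCondition",
    "ProtocolConfig",
    "VoltageProtocol",
    "build_seventeen_pulse_protocol",
    "condition_of",
]

ROLE_TEST_PULSE = "test_pulse"
ROLE_CONDITIONING = "conditioning"
ROLE_GAP = "gap"
ROLE_HOLDING = "holding"
_ROLES = (ROLE_TEST_PULSE, ROLE_CONDITIONING, ROLE_GAP, ROLE_HOLDING)

SECTION_SDO = "SDO"
SECTION_RFI = "RFI"
SECTION_SSI = "SSI"


@dataclass(frozen=True)
class VoltageSegment:
    """One constant-voltage command segment."""

    duration_ms: float
    voltage_mV: float
    role: str
    pulse_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration_ms}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")
        if (self.pulse_index is not None) != (self.role == ROLE_TEST_PULSE):
            raise ValueError("pulse_index must be present iff role == 'test_pulse'")
        if self.pulse_index is not None and not (1 <= self.pulse_index <= 17):
            raise ValueError(f"pulse_index out of range: {self.pulse_index}")


@dataclass(frozen=True)
class PulseCondition:
    """Section membership and EIP x-axis value(s) for one test pulse.

    A pulse may belong to more than one section (pulse #12 sits in both RFI
    and SSI; pulse #1 is the rested baseline and the longest RFI point).
    """

    pulse_index: int
    sections: tuple[str, ...]
    is_rested_baseline: bool = False
    conditioning_ms: Optional[float] = None  # SDO x-axis
    gap_ms: Optional[float] = None           # RFI x-axis (preceding hyperpolarization)
    holding_mV: Optional[float] = None       # SSI x-axis

    def x_value(self, section: str) -> float:
        if section == SECTION_SDO and self.conditioning_ms is not None:
            return self.conditioning_ms
        if section == SECTION_RFI and self.gap_ms is not None:
            return self.gap_ms
        if section == SECTION_SSI and self.holding_mV is not None:
            return self.holding_mV
        raise KeyError(
            f"pulse #{self.pulse_index} has no x-value for section {section!r}"
        )


# Default RFI gap->pulse assignment.  Pulse #7 follows the 1 ms gap (the
# shortest recovery interval), gaps then double up to #12; pulse #6 follows the
# 64 ms gap after the SDO block and pulse #1 follows the 498 ms inter-sweep
# interval, making it the rested baseline.
DEFAULT_RFI_GAP_MAP: dict[int, float] = {
    7: 1.0, 8: 2.0, 9: 4.0, 10: 8.0, 11: 16.0, 12: 32.0, 6: 64.0, 1: 498.0,
}


@dataclass
class ProtocolConfig:
    """Configuration of the 17-pulse protocol.

    Defaults give a sweep whose segment durations sum to exactly 1000 ms so
    that at 1 Hz the physical gap preceding pulse #1 equals its nominal 498 ms
    recovery interval.
    """

    holding_mV: float = -130.0
    test_mV: float = -10.0
    test_pulse_ms: float = 5.0
    sweep_period_ms: float = 1000.0
    # SDO: independent conditioning prepulses, each followed by a short gap.
    sdo_conditioning_ms: tuple[float, ...] = (2.5, 7.5, 22.5, 67.5)
    sdo_gap_ms: float = 2.5
    sdo_recovery_ms: float = 20.0
    # RFI: gap (ms) preceding each RFI pulse; the entry for pulse 1 is the
    # terminal hyperpolarized interval closing the sweep.
    rfi_gap_map: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RFI_GAP_MAP)
    )
    # SSI: holding levels for pulses #13..#17 (pulse #12 sits at holding_mV).
    ssi_levels_mV: tuple[float, ...] = (-110.0, -100.0, -90.0, -80.0, -70.0)
    ssi_equilibration_ms: float = 20.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rfi_gap_map"] = {str(k): v for k, v in self.rfi_gap_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolConfig":
        d = dict(d)
        if "rfi_gap_map" in d:
            d["rfi_gap_map"] = {int(k): float(v) for k, v in d["rfi_gap_map"].items()}
        for key in ("sdo_conditioning_ms", "ssi_levels_mV"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class VoltageProtocol:
    segments: tuple[VoltageSegment, ...]
    sweep_period_ms: float
    condition_map: dict[int, PulseCondition]

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        indices = [s.pulse_index for s in self.segments if s.role == ROLE_TEST_PULSE]
        if len(indices) == 0:
            raise ValueError("protocol has no test pulses")
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate test-pulse indices")
        total = sum(s.duration_ms for s in self.segments)
        if total > self.sweep_period_ms + 1e-9:
            raise ValueError(
                f"segment durations sum to {total:.3f} ms, exceeding the "
                f"{self.sweep_period_ms:.3f} ms sweep period"
            )
        missing = set(indices) - set(self.condition_map)
        if missing:
            raise ValueError(f"pulses missing from condition_map: {sorted(missing)}")

    @property
    def pulse_indices(self) -> tuple[int, ...]:
        return tuple(
            s.pulse_index for s in self.segments if s.role == ROLE_TEST_PULSE
        )

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_indices)

    def total_segment_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    def segment_starts(self) -> list[float]:
        t, out = 0.0, []
        for s in self.segments:
            out.append(t)
            t += s.duration_ms
        return out

    def test_pulse_windows(self) -> dict[int, tuple[float, float]]:
        """Absolute ``[start, end)`` time of each test pulse within the sweep."""
        out: dict[int, tuple[float, float]] = {}
        t = 0.0
        for s in self.segments:
            if s.role == ROLE_TEST_PULSE:
                out[s.pulse_index] = (t, t + s.duration_ms)
            t += s.duration_ms
        return out

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "duration_ms": [s.duration_ms for s in self.segments],
                "voltage_mV": [s.voltage_mV for s in self.segments],
                "role": [s.role for s in self.segments],
                "pulse_index": [
                    s.pulse_index if s.pulse_index is not None else -1
                    for s in self.segments
                ],
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sweep_period_ms: float,
        condition_map: dict[int, PulseCondition],
    ) -> "VoltageProtocol":
        segs = tuple(
            VoltageSegment(
                duration_ms=float(r.duration_ms),
                voltage_mV=float(r.voltage_mV),
                role=str(r.role),
                pulse_index=None if int(r.pulse_index) < 0 else int(r.pulse_index),
            )
            for r in frame.itertuples()
        )
        return cls(segs, sweep_period_ms, condition_map)

    def to_dict(self) -> dict:
        return {
            "sweep_period_ms": self.sweep_period_ms,
            "segments": [
                {
                    "duration_ms": s.duration_ms,
                    "voltage_mV": s.voltage_mV,
                    "role": s.role,
                    "pulse_index": s.pulse_index,
                }
                for s in self.segments
            ],
            "condition_map": {
                str(k): {
                    "pulse_index": c.pulse_index,
                    "sections": list(c.sections),
                    "is_rested_baseline": c.is_rested_baseline,
                    "conditioning_ms": c.conditioning_ms,
                    "gap_ms": c.gap_ms,
                    "holding_mV": c.holding_mV,
                }
                for k, c in self.condition_map.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VoltageProtocol":
        segs = tuple(
            VoltageSegment(
                duration_ms=float(s["duration_ms"]),
                voltage_mV=float(s["voltage_mV"]),
                role=str(s["role"]),
                pulse_index=s["pulse_index"],
            )
            for s in d["segments"]
        )
        cmap = {
            int(k): PulseCondition(
                pulse_index=int(c["pulse_index"]),
                sections=tuple(c["sections"]),
                is_rested_baseline=bool(c["is_rested_baseline"]),
                conditioning_ms=c["conditioning_ms"],
                gap_ms=c["gap_ms"],
                holding_mV=c["holding_mV"],
            )
            for k, c in d["condition_map"].items()
        }
        return cls(segs, float(d["sweep_period_ms"]), cmap)


def _check_positive_increasing(name: str, values: Sequence[float]) -> None:
    vals = list(values)
    if any(v <= 0 for v in vals):
        raise ValueError(f"{name} must all be > 0, got {vals}")
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError(f"{name} must be strictly increasing, got {vals}")


def build_seventeen_pulse_protocol(
    config: Optional[ProtocolConfig] = None,
) -> VoltageProtocol:
    """Build the 17-pulse SDO/RFI/SSI protocol.

    Layout (default config, 1000 ms sweep at 1 Hz):

    * pulse #1 — rested baseline, fired right after the 498 ms terminal
      hyperpolarized interval of the previous sweep (longest RFI point);
    * pulses #2–#5 — SDO: conditioning depolarizations of 2.5/7.5/22.5/67.5 ms,
      each followed by a 2.5 ms hyperpolarizing gap and the test pulse;
    * pulses #6–#12 — RFI: hyperpolarizing gaps (default 64, 1, 2, 4, 8, 16,
      32 ms, in protocol order) separated by the 5 ms test depolarizations;
    * pulses #12–#17 — SSI: test pulses from holding levels −130 … −70 mV
      after a per-level equilibration interval.
    """
    cfg = config or ProtocolConfig()
    _check_positive_increasing("SDO conditioning durations", cfg.sdo_conditioning_ms)
    if len(cfg.sdo_conditioning_ms) != 4:
        raise ValueError("expected 4 SDO conditioning durations (pulses #2-#5)")
    if set(cfg.rfi_gap_map) != {1, 6, 7, 8, 9, 10, 11, 12}:
        raise ValueError(
            "rfi_gap_map must assign gaps to pulses {1, 6..12}, got "
            f"{sorted(cfg.rfi_gap_map)}"
        )
    if any(g <= 0 for g in cfg.rfi_gap_map.values()):
        raise ValueError("RFI gap durations must be strictly positive")
    if len(cfg.ssi_levels_mV) != 5:
        raise ValueError("expected 5 SSI holding levels (pulses #13-#17)")
    _check_positive_increasing("SSI holding levels (as offsets)",
                               [v - cfg.ssi_levels_mV[0] + 1 for v in cfg.ssi_levels_mV])
    for name, v in (
        ("test_pulse_ms", cfg.test_pulse_ms),
        ("sdo_gap_ms", cfg.sdo_gap_ms),
        ("sdo_recovery_ms", cfg.sdo_recovery_ms),
        ("ssi_equilibration_ms", cfg.ssi_equilibration_ms),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")

    segs: list[VoltageSegment] = []

    def test(idx: int) -> None:
        segs.append(
            VoltageSegment(cfg.test_pulse_ms, cfg.test_mV, ROLE_TEST_PULSE, idx)
        )

    # pulse #1: rested baseline at sweep start
    test(1)
    # SDO block
    for i, dur in enumerate(cfg.sdo_conditioning_ms, start=2):
        segs.append(VoltageSegment(cfg.sdo_recovery_ms, cfg.holding_mV, ROLE_HOLDING))
        segs.append(VoltageSegment(dur, cfg.test_mV, ROLE_CONDITIONING))
        segs.append(VoltageSegment(cfg.sdo_gap_ms, cfg.holding_mV, ROLE_GAP))
        test(i)
    # RFI block: pulses 6..12 in protocol order, each preceded by its gap
    for p in range(6, 13):
        segs.append(VoltageSegment(cfg.rfi_gap_map[p], cfg.holding_mV, ROLE_GAP))
        test(p)
    # SSI block: pulses 13..17 from progressively depolarized holding levels
    for p, level in zip(range(13, 18), cfg.ssi_levels_mV):
        segs.append(VoltageSegment(cfg.ssi_equilibration_ms, level, ROLE_HOLDING))
        test(p)
    # terminal hyperpolarized interval = the RFI recovery interval of pulse #1
    segs.append(VoltageSegment(cfg.rfi_gap_map[1], cfg.holding_mV, ROLE_HOLDING))

    cmap: dict[int, PulseCondition] = {
        1: PulseCondition(1, (SECTION_RFI,), is_rested_baseline=True,
                          gap_ms=cfg.rfi_gap_map[1]),
    }
    for i, dur in enumerate(cfg.sdo_conditioning_ms, start=2):
        cmap[i] = PulseCondition(i, (SECTION_SDO,), conditioning_ms=dur)
    for p in range(6, 12):
        cmap[p] = PulseCondition(p, (SECTION_RFI,), gap_ms=cfg.rfi_gap_map[p])
    cmap[12] = PulseCondition(
        12, (SECTION_RFI, SECTION_SSI),
        gap_ms=cfg.rfi_gap_map[12], holding_mV=cfg.holding_mV,
    )
    for p, level in zip(range(13, 18), cfg.ssi_levels_mV):
        cmap[p] = PulseCondition(p, (SECTION_SSI,), holding_mV=level)

    proto = VoltageProtocol(tuple(segs), cfg.sweep_period_ms, cmap)
    if proto.n_pulses != 17:
        raise AssertionError("protocol construction yielded != 17 test pulses")
    return proto


def condition_of(protocol: VoltageProtocol, pulse_index: int) -> PulseCondition:
    """Section membership(s) and EIP x-axis value(s) for one pulse."""
    try:
        return protocol.condition_map[int(pulse_index)]
    except KeyError:
        raise KeyError(f"unknown pulse_index {pulse_index}") from None
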