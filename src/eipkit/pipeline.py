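"""End-to-end orchestration: simulate -> amplitude tables -> EIP -> summary.

These functions are the library's high-level entry points (used by the
example scripts): :func:`run_simulate` writes a simulated experiment plus its
ground-truth sidecar, :func:`run_analyze` turns amplitude tables into EIP
curves and compound summaries, and :func:`make_fixtures` emits the bundled
mechanism presets as small ready-to-analyze datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .channel import ChannelModel, CompoundMechanism
from .eip import EIPCurve
from .presets import (
    COMPOUND_PRESETS,
    compound_preset,
    generic_fast_nav,
    preset_concentrations_uM,
)
from .protocol import ProtocolConfig, VoltageProtocol, build_seventeen_pulse_protocol
from .simulate import NoiseModel, SimulatedExperiment, simulate_experiment
from .summary import CompoundSummary, group_summary, summarize_measurement
from .traces import annotate_phases

__all__ = [
    "RunConfig",
    "default_schedule",
    "washout_slice",
    "run_simulate",
    "run_analyze",
    "make_fixtures",
]


def default_schedule(
    concentrations_uM: Sequence[float],
    n_control: int = 15,
    n_drug: int = 20,
    n_washout: int = 40,
) -> tuple[tuple[int, float], ...]:
    """Perfusion schedule: a drug-free control block before each application,
    applications in ascending concentration order, and a terminal washout."""
    blocks: list[tuple[int, float]] = []
    for c in sorted(concentrations_uM):
        if c <= 0:
            raise ValueError("concentrations must be > 0")
        blocks.append((n_control, 0.0))
        blocks.append((n_drug, float(c)))
    blocks.append((n_washout, 0.0))
    return tuple(blocks)


@dataclass
class RunConfig:
    """Everything needed for a deterministic simulate-and-analyze run."""

    mechanism: CompoundMechanism
    concentrations_uM: tuple[float, ...]
    seed: int
    protocol_config: ProtocolConfig = field(default_factory=ProtocolConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_control: int = 15
    n_drug: int = 20
    n_washout: int = 40
    control_window_s: float = 5.0
    drug_window_s: float = 5.0
    conductance_scale_nA: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic runs")
        if len(self.concentrations_uM) < 3:
            raise ValueError("at least 3 concentrations are required for EIP fits")

    def schedule(self) -> tuple[tuple[int, float], ...]:
        return default_schedule(
            self.concentrations_uM, self.n_control, self.n_drug, self.n_washout
        )

    def protocol(self) -> VoltageProtocol:
        return build_seventeen_pulse_protocol(self.protocol_config)

    def channel(self) -> ChannelModel:
        return generic_fast_nav(self.conductance_scale_nA)

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism.to_dict(),
            "concentrations_uM": list(self.concentrations_uM),
            "seed": self.seed,
            "protocol_config": self.protocol_config.to_dict(),
            "noise": {
                "multiplicative_sd": self.noise.multiplicative_sd,
                "rundown_per_sweep": self.noise.rundown_per_sweep,
            },
            "n_control": self.n_control,
            "n_drug": self.n_drug,
            "n_washout": self.n_washout,
            "control_window_s": self.control_window_s,
            "drug_window_s": self.drug_window_s,
            "conductance_scale_nA": self.conductance_scale_nA,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        required = {"mechanism", "concentrations_uM", "seed"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"run config is missing fields: {sorted(missing)}")
        return cls(
            mechanism=CompoundMechanism.from_dict(d["mechanism"]),
            concentrations_uM=tuple(d["concentrations_uM"]),
            seed=int(d["seed"]),
            protocol_config=ProtocolConfig.from_dict(d.get("protocol_config", {})),
            noise=NoiseModel(**d.get("noise", {})),
            n_control=int(d.get("n_control", 15)),
            n_drug=int(d.get("n_drug", 20)),
            n_washout=int(d.get("n_washout", 40)),
            control_window_s=float(d.get("control_window_s", 5.0)),
            drug_window_s=float(d.get("drug_window_s", 5.0)),
            conductance_scale_nA=float(d.get("conductance_scale_nA", 10.0)),
        )


def washout_slice(
    amplitudes: pd.DataFrame, schedule: Sequence[tuple[int, float]]
) -> pd.DataFrame:
    """Rows belonging to the terminal washout (sweeps after the last
    application block)."""
    start = 0
    last_app_end = None
    for n, c in schedule:
        if c > 0:
            last_app_end = start + n
        start += n
    if last_app_end is None:
        raise ValueError("schedule contains no application")
    return amplitudes[amplitudes["sweep_index"] >= last_app_end]


def simulate_measurement(
    config: RunConfig, seed: Optional[int] = None
) -> SimulatedExperiment:
    """Simulate one cell-ensemble measurement under the configured schedule."""
    return simulate_experiment(
        channel=config.channel(),
        drug=config.mechanism,
        protocol=config.protocol(),
        schedule=config.schedule(),
        noise=config.noise,
        seed=config.seed if seed is None else seed,
    )


def run_simulate(config: RunConfig, outdir) -> dict[str, Path]:
    """Simulate and write amplitude table + ground-truth sidecar + protocol."""
    outdir = Path(outdir)
    exp = simulate_measurement(config)
    provenance = {
        "seed": config.seed,
        "config_hash": eio.config_hash(config.to_dict()),
    }
    paths = {
        "amplitudes": outdir / "amplitudes.csv",
        "ground_truth": outdir / "ground_truth.json",
        "protocol": outdir / "protocol.json",
        "run_config": outdir / "run_config.json",
    }
    eio.write_amplitudes(exp.amplitudes, paths["amplitudes"], provenance)
    eio.write_json(exp.ground_truth(), paths["ground_truth"])
    eio.write_protocol_config(exp.protocol, paths["protocol"])
    eio.write_json(config.to_dict(), paths["run_config"])
    return paths


def analyze_measurement(
    amplitudes: pd.DataFrame,
    config: RunConfig,
    measurement_id: str = "",
) -> tuple[CompoundSummary, dict[str, EIPCurve]]:
    """Annotate phases and run the full per-measurement analysis."""
    protocol = config.protocol()
    schedule = config.schedule()
    annotated = annotate_phases(
        amplitudes, schedule,
        control_window_s=config.control_window_s,
        drug_window_s=config.drug_window_s,
        sweep_period_s=protocol.sweep_period_ms / 1000.0,
    )
    washout = washout_slice(amplitudes, schedule)
    return summarize_measurement(
        annotated, protocol,
        measurement_id=measurement_id,
        compound=config.mechanism.name,
        washout_amplitudes=washout if len(washout) >= 10 else None,
    )


def _eip_long_table(
    curves_by_measurement: Mapping[str, Mapping[str, EIPCurve]]
) -> pd.DataFrame:
    rows = []
    for mid, curves in curves_by_measurement.items():
        for section, curve in curves.items():
            for r in curve.points.itertuples():
                rows.append(
                    (mid, section, r.x, curve.x_unit, r.pulse_index,
                     r.ic50, r.ic50_se, r.n_h, r.nh_se, r.flag)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "measurement_id", "section", "x_value", "x_unit", "pulse_index",
            "IC50_uM", "IC50_se", "nH", "nH_se", "quality_flag",
        ],
    )


def _table1_style(summaries: Sequence[CompoundSummary]) -> pd.DataFrame:
    """One column per compound, descriptor rows as in a results table."""
    cols = {}
    by_compound: dict[str, list[CompoundSummary]] = {}
    for s in summaries:
        by_compound.setdefault(s.compound or "compound", []).append(s)
    for comp, ss in by_compound.items():
        g = group_summary(ss)
        sc = g.scalars

        def fmt(name):
            return f"{sc.loc[name, 'geo_mean']:.4g}"

        onset = [s.micro_onset for s in ss if s.micro_onset is not None
                 and s.micro_onset.detectable]
        offset = [s.micro_offset for s in ss if s.micro_offset is not None
                  and s.micro_offset.detectable]
        taus = [s.tau_macro_off_s for s in ss if np.isfinite(s.tau_macro_off_s)]

        def geo_pulse(p):
            vals = [s.ic50_by_pulse[p] for s in ss if p in s.ic50_by_pulse]
            return f"{np.exp(np.mean(np.log(vals))):.4g}" if vals else "n.d."

        cols[comp] = {
            "IC50 #1 (estimated K_R) (uM)": fmt("K_R_uM"),
            "IC50 #5 (longest conditioning) (uM)": geo_pulse(5),
            "IC50 #7 (after 1 ms gap) (uM)": geo_pulse(7),
            "IC50 #17 (-70 mV) (uM)": fmt("K_app_uM"),
            "K_I (calculated) (uM)": fmt("K_I_uM"),
            "K_R/K_I ratio": fmt("K_R_over_K_I"),
            "macro-offset time constant (s)":
                f"{np.mean(taus):.4g}" if taus else "n.d.",
            "micro-onset range (ms)":
                f"{min(m.t_lo_snapped_ms for m in onset):g}-"
                f"{max(m.t_hi_snapped_ms for m in onset):g}" if onset else "flat",
            "micro-offset range (ms)":
                f"{min(m.t_lo_snapped_ms for m in offset):g}-"
                f"{max(m.t_hi_snapped_ms for m in offset):g}" if offset else "flat",
        }
    return pd.DataFrame(cols)


def run_analyze(
    amplitude_paths: Sequence, config: RunConfig, outdir
) -> dict[str, Path]:
    """Analyze one or more measurements and write EIP + summary reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries: list[CompoundSummary] = []
    curves_by_measurement: dict[str, dict[str, EIPCurve]] = {}
    for i, p in enumerate(amplitude_paths, start=1):
        amplitudes = eio.read_amplitudes(p)
        mid = f"m{i:02d}"
        summ, curves = analyze_measurement(amplitudes, config, measurement_id=mid)
        summaries.append(summ)
        curves_by_measurement[mid] = curves

    group = group_summary(
        summaries, curves_by_measurement=list(curves_by_measurement.values())
    )
    provenance = {
        "seed": config.seed,
        "config_hash": eio.config_hash(config.to_dict()),
    }
    paths = {
        "eip_curves": outdir / "eip_curves.csv",
        "summary": outdir / "summary.json",
        "table": outdir / "summary_table.csv",
    }
    eio._write_csv_with_header(
        _eip_long_table(curves_by_measurement), paths["eip_curves"], provenance
    )
    eio.write_json(
        {
            "measurements": [s.to_dict() for s in summaries],
            "group": {
                "n": group.n,
                "scalars": group.scalars.to_dict(),
                "K_R_over_K_I_ratio_of_means": group.ratio_of_means,
            },
        },
        paths["summary"],
    )
    _table1_style(summaries).to_csv(paths["table"])
    return paths


def make_fixtures(seed: int, outdir) -> dict[str, dict[str, Path]]:
    """Emit the five bundled mechanism presets as small simulated datasets.

    For each preset: the mechanism sidecar, a short simulated experiment's
    amplitude table, and the run configuration used to generate it.
    """
    outdir = Path(outdir)
    out: dict[str, dict[str, Path]] = {}
    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(len(COMPOUND_PRESETS))]
    for s_i, name in zip(child_seeds, sorted(COMPOUND_PRESETS)):
        mech = compound_preset(name)
        # block lengths scale with the perfusion time constant so the tagged
        # windows sit at (approximate) bath equilibrium
        n_block = 12 + int(np.ceil(3.0 * mech.perfusion_tau_s))
        cfg = RunConfig(
            mechanism=mech,
            concentrations_uM=preset_concentrations_uM(name),
            seed=s_i,
            n_control=n_block,
            n_drug=n_block,
            n_washout=max(20, n_block),
        )
        paths = run_simulate(cfg, outdir / name)
        eio.write_mechanism(cfg.mechanism, outdir / name / "mechanism.json")
        paths["mechanism"] = outdir / name / "mechanism.json"
        out[name] = paths
    return out
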