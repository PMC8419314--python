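"""Compound-level, concentration-independent descriptors.

From the per-pulse EIP fits this module derives the quantities that
characterize a compound irrespective of the concentrations used:

* ``K_R`` — resting-state dissociation constant, approximated by the IC50 of
  the rested-baseline pulse (#1);
* ``K_I`` — inactivated-state dissociation constant, obtained from the
  apparent affinity at depolarized holding (IC50 of pulse #17 at −70 mV) via
  the two-state affinity mixture

      1/K_app = (1 − h)/K_R + h/K_I

  where ``h`` is the fraction of channels inactivated at −70 mV (from the
  17th/1st pulse control-amplitude ratio);
* the K_R/K_I ratio (degree of state dependence);
* the macro-offset time constant (second-scale recovery upon washout);
* micro-onset and micro-offset time ranges (millisecond-scale EIP change
  along the SDO and RFI axes).

Also included: the ensemble QC/exclusion filter, geometric-mean group
summaries, and the EIP-over-firing overlay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .eip import EIPCurve, build_eip_curves, make_ratio_table
from .protocol import VoltageProtocol

__all__ = [
    "AffinityEstimate",
    "MacroOffsetFit",
    "MicroRange",
    "QCResult",
    "CompoundSummary",
    "GroupSummary",
    "EIPTimecourse",
    "fraction_inactivated",
    "estimate_affinities",
    "macro_offset_tau",
    "micro_range",
    "qc_filter",
    "group_summary",
    "summarize_measurement",
    "overlay_eip",
    "MICRO_RANGE_GRID_MS",
]

# Table-style reporting grid for micro-dynamics ranges (ms)
MICRO_RANGE_GRID_MS = (0.1, 1.0, 2.0, 4.0, 10.0, 100.0, 500.0, 1000.0)


# ---------------------------------------------------------------------------
# h and affinities
# ---------------------------------------------------------------------------

def fraction_inactivated(
    amplitudes: pd.DataFrame,
    application: int = 1,
    pulse_rested: int = 1,
    pulse_depolarized: int = 17,
) -> float:
    """Fraction of channels inactivated at the depolarized holding level.

    ``h = 1 − mean|peak #17| / mean|peak #1|`` over the tagged control window
    of the given application (the last seconds of drug-free recording before
    that application), clipped to [0, 1].
    """
    ctrl = amplitudes[amplitudes["phase"] == f"control_{application}"]
    if ctrl.empty:
        raise ValueError(f"no control sweeps tagged for application {application}")
    if ctrl["sweep_index"].nunique() < 5:
        raise ValueError("at least 5 control sweeps are required to estimate h")
    means = ctrl.groupby("pulse_index")["amplitude_nA"].apply(
        lambda a: np.abs(a).mean()
    )
    for p in (pulse_rested, pulse_depolarized):
        if p not in means.index:
            raise ValueError(f"pulse #{p} missing from control sweeps")
    if means[pulse_rested] == 0:
        raise ValueError(f"control mean amplitude of pulse #{pulse_rested} is zero")
    h = 1.0 - means[pulse_depolarized] / means[pulse_rested]
    return float(np.clip(h, 0.0, 1.0))


@dataclass(frozen=True)
class AffinityEstimate:
    K_R: float
    K_I: float
    K_app: float
    h: float
    ratio: float
    flags: tuple[str, ...] = ()


def estimate_affinities(
    ic50_rested: float, ic50_depolarized: float, h: float
) -> AffinityEstimate:
    """State affinities from rested and depolarized-holding IC50s.

    ``K_R = IC50(#1)``.  ``K_I`` inverts the two-state affinity mixture for
    the apparent affinity at the depolarized holding, where the *available*
    fraction weights K_R and the inactivated fraction ``h`` weights K_I:

        1/K_app = (1 − h)/K_R + h/K_I,   K_app = IC50(#17)

    giving ``K_I = h / (1/K_app − (1 − h)/K_R)``.  ``h = 0`` (no channels
    inactivated at the depolarized holding) leaves K_I unidentifiable and is
    an error; a non-positive denominator (K_app larger than the mixture can
    produce for any positive K_I) returns a flagged estimate with
    ``K_I = nan``.
    """
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"h must be in [0, 1], got {h}")
    if h == 0.0:
        raise ValueError("h = 0: no channels inactivated, K_I is unidentifiable")
    if ic50_rested <= 0 or ic50_depolarized <= 0:
        raise ValueError("IC50s must be > 0")
    K_R, K_app = float(ic50_rested), float(ic50_depolarized)
    denom = 1.0 / K_app - (1.0 - h) / K_R
    if denom <= 0:
        return AffinityEstimate(
            K_R=K_R, K_I=np.nan, K_app=K_app, h=h, ratio=np.nan,
            flags=("inconsistent_estimates",),
        )
    K_I = h / denom
    return AffinityEstimate(K_R=K_R, K_I=float(K_I), K_app=K_app, h=h,
                            ratio=float(K_R / K_I))


def apparent_affinity(K_R: float, K_I: float, h: float) -> float:
    """Forward form of the two-state affinity mixture: K_app from K_R, K_I
    and the inactivated fraction h."""
    return 1.0 / ((1.0 - h) / K_R + h / K_I)


# ---------------------------------------------------------------------------
# macro-offset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MacroOffsetFit:
    tau_s: float
    plateau_nA: float
    delta_nA: float
    flags: tuple[str, ...] = ()


def macro_offset_tau(
    washout_amplitudes: pd.DataFrame, pulse_index: int = 17
) -> MacroOffsetFit:
    """Single-exponential fit of peak-amplitude recovery after washout.

    Fits ``|A|(t) = A_inf − dA·exp(−t/tau)`` to the chosen pulse's absolute
    peaks against time (seconds, relative to the first washout sweep).  A
    series that does not recover (fitted amplitude step <= 0, or essentially
    constant) is returned flagged with ``tau = nan``.
    """
    sel = washout_amplitudes[washout_amplitudes["pulse_index"] == pulse_index]
    if sel["sweep_index"].nunique() < 10:
        raise ValueError("at least 10 washout sweeps are required")
    sel = sel.sort_values("time_s")
    t = sel["time_s"].to_numpy(dtype=float)
    t = t - t[0]
    y = np.abs(sel["amplitude_nA"].to_numpy(dtype=float))

    if np.ptp(y) < 1e-12 or np.ptp(y) < 0.01 * max(np.abs(y).max(), 1e-12):
        return MacroOffsetFit(np.nan, float(y.mean()), 0.0, ("non_recovering",))

    def model(tt, a_inf, da, tau):
        return a_inf - da * np.exp(-tt / tau)

    p0 = [y[-5:].mean(), y[-5:].mean() - y[:3].mean(), max(t[-1] / 3.0, 1e-3)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, y, p0=p0,
                bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
    except RuntimeError:
        return MacroOffsetFit(np.nan, float(y.mean()), 0.0, ("fit_failed",))
    a_inf, da, tau = popt
    if da <= 0:
        return MacroOffsetFit(np.nan, float(a_inf), float(da), ("non_recovering",))
    return MacroOffsetFit(float(tau), float(a_inf), float(da))


# ---------------------------------------------------------------------------
# micro-dynamics range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroRange:
    t_lo_ms: float
    t_hi_ms: float
    t_lo_snapped_ms: float
    t_hi_snapped_ms: float
    fold_span: float
    flags: tuple[str, ...] = ()

    @property
    def detectable(self) -> bool:
        return "flat" not in self.flags


def _snap(value: float, grid: Sequence[float], direction: str) -> float:
    grid = sorted(grid)
    if direction == "down":
        cands = [g for g in grid if g <= value + 1e-12]
        return cands[-1] if cands else grid[0]
    cands = [g for g in grid if g >= value - 1e-12]
    return cands[0] if cands else grid[-1]


def micro_range(
    curve: EIPCurve,
    lo: float = 0.1,
    hi: float = 0.9,
    min_fold: float = 1.5,
    grid_ms: Sequence[float] = MICRO_RANGE_GRID_MS,
) -> MicroRange:
    """Time range over which the EIP changes along a (log-time) curve.

    Progress is measured as the fraction of the total log-IC50 span between
    the curve's first and last points; the returned bounds are the
    (log-linearly interpolated) times at which progress crosses ``lo`` and
    ``hi``.  Snapped bounds land on the table-style reporting grid (outward).
    A curve whose total IC50 span is below ``min_fold`` carries no detectable
    micro-dynamics and is returned flagged ``flat``.
    """
    if len(curve.points) < 3:
        raise ValueError("micro_range needs a curve with >= 3 points")
    x = curve.x
    y = np.log(curve.ic50)
    fold = float(np.exp(np.abs(y.max() - y.min())))
    if fold < min_fold:
        return MicroRange(np.nan, np.nan, np.nan, np.nan, fold, ("flat",))
    span = y[-1] - y[0]
    if span == 0:
        return MicroRange(np.nan, np.nan, np.nan, np.nan, fold, ("flat",))
    prog = (y - y[0]) / span
    prog = np.maximum.accumulate(np.clip(prog, 0.0, 1.0))
    logx = np.log(x)

    def cross(level: float) -> float:
        idx = int(np.argmax(prog >= level))
        if prog[idx] < level:
            return float(x[-1])
        if idx == 0:
            return float(x[0])
        f = (level - prog[idx - 1]) / (prog[idx] - prog[idx - 1])
        return float(np.exp(logx[idx - 1] + f * (logx[idx] - logx[idx - 1])))

    t_lo, t_hi = cross(lo), cross(hi)
    return MicroRange(
        t_lo_ms=t_lo,
        t_hi_ms=t_hi,
        t_lo_snapped_ms=_snap(t_lo, grid_ms, "down"),
        t_hi_snapped_ms=_snap(t_hi, grid_ms, "up"),
        fold_span=fold,
    )


# ---------------------------------------------------------------------------
# QC / exclusion
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    included: list
    table: pd.DataFrame  # per-ensemble: ensemble_id, included, reason


def qc_filter(
    metrics: pd.DataFrame,
    n_select: int = 6,
    min_amplitude_nA: float = 2.0,
    min_seal_MOhm: float = 80.0,
    max_seal_loss_pct: float = 20.0,
) -> QCResult:
    """Apply ensemble exclusion rules, then keep the best ``n_select``.

    ``metrics`` needs columns ``ensemble_id, control_amplitude_nA,
    seal_resistance_MOhm, seal_loss_pct, sudden_drop`` (bool); an optional
    ``seal_resistance_sd_MOhm`` column is used as the stability tie-breaker.
    Exclusion rules: control amplitude below ``min_amplitude_nA``; mean seal
    resistance below ``min_seal_MOhm``; gradual seal loss above
    ``max_seal_loss_pct``; a sudden amplitude drop with concurrent seal drop.
    Survivors are ranked by (seal resistance, stability) and the top
    ``n_select`` are included; fewer survivors than requested produces a
    warning, not an error.
    """
    required = {
        "ensemble_id", "control_amplitude_nA", "seal_resistance_MOhm",
        "seal_loss_pct", "sudden_drop",
    }
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table is missing columns: {sorted(missing)}")

    reasons = []
    for r in metrics.itertuples():
        if abs(r.control_amplitude_nA) < min_amplitude_nA:
            reasons.append(f"amplitude < {min_amplitude_nA:g} nA")
        elif r.seal_resistance_MOhm < min_seal_MOhm:
            reasons.append(f"seal resistance < {min_seal_MOhm:g} MOhm")
        elif r.seal_loss_pct > max_seal_loss_pct:
            reasons.append(f"seal loss > {max_seal_loss_pct:g}%")
        elif bool(r.sudden_drop):
            reasons.append("sudden amplitude drop with seal resistance drop")
        else:
            reasons.append("")
    out = metrics.copy()
    out["reason"] = reasons
    survivors = out[out["reason"] == ""].copy()
    if "seal_resistance_sd_MOhm" in survivors.columns:
        survivors = survivors.sort_values(
            ["seal_resistance_MOhm", "seal_resistance_sd_MOhm"],
            ascending=[False, True],
        )
    else:
        survivors = survivors.sort_values("seal_resistance_MOhm", ascending=False)
    if len(survivors) < n_select:
        warnings.warn(
            f"only {len(survivors)} ensembles pass QC (requested {n_select}); "
            "returning all survivors",
            stacklevel=2,
        )
    included = survivors["ensemble_id"].head(n_select).tolist()
    out["included"] = out["ensemble_id"].isin(included)
    return QCResult(included=included, table=out)


# ---------------------------------------------------------------------------
# per-measurement and group summaries
# ---------------------------------------------------------------------------

@dataclass
class CompoundSummary:
    """Concentration-independent descriptors of one measurement."""

    measurement_id: str
    compound: str
    K_R: float
    K_I: float
    K_app: float
    h: float
    ratio: float
    ic50_by_pulse: dict[int, float] = field(default_factory=dict)
    nh_by_pulse: dict[int, float] = field(default_factory=dict)
    tau_macro_off_s: float = np.nan
    micro_onset: Optional[MicroRange] = None
    micro_offset: Optional[MicroRange] = None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def mr(m: Optional[MicroRange]):
            if m is None:
                return None
            return {
                "t_lo_ms": m.t_lo_ms, "t_hi_ms": m.t_hi_ms,
                "t_lo_snapped_ms": m.t_lo_snapped_ms,
                "t_hi_snapped_ms": m.t_hi_snapped_ms,
                "fold_span": m.fold_span, "flags": list(m.flags),
            }

        return {
            "measurement_id": self.measurement_id,
            "compound": self.compound,
            "K_R_uM": self.K_R,
            "K_I_uM": self.K_I,
            "K_app_uM": self.K_app,
            "h": self.h,
            "K_R_over_K_I": self.ratio,
            "ic50_by_pulse_uM": {str(k): v for k, v in self.ic50_by_pulse.items()},
            "nH_by_pulse": {str(k): v for k, v in self.nh_by_pulse.items()},
            "tau_macro_off_s": self.tau_macro_off_s,
            "micro_onset_range_ms": mr(self.micro_onset),
            "micro_offset_range_ms": mr(self.micro_offset),
            "flags": list(self.flags),
        }


def summarize_measurement(
    annotated_amplitudes: pd.DataFrame,
    protocol: VoltageProtocol,
    measurement_id: str = "",
    compound: str = "",
    washout_amplitudes: Optional[pd.DataFrame] = None,
) -> tuple[CompoundSummary, dict[str, EIPCurve]]:
    """Full per-measurement analysis: ratios -> EIP curves -> descriptors."""
    ratios = make_ratio_table(annotated_amplitudes)
    curves = build_eip_curves(ratios, protocol, measurement_id=measurement_id)
    h = fraction_inactivated(annotated_amplitudes)
    rested = curves["RFI"].ic50_of_pulse(1)
    depol = curves["SSI"].ic50_of_pulse(17)
    aff = estimate_affinities(rested, depol, h)

    fits_by_pulse: dict[int, float] = {}
    nh_by_pulse: dict[int, float] = {}
    for c in curves.values():
        for r in c.points.itertuples():
            fits_by_pulse[int(r.pulse_index)] = float(r.ic50)
            nh_by_pulse[int(r.pulse_index)] = float(r.n_h)

    flags = list(aff.flags)
    onset = offset = None
    if "SDO" in curves:
        onset = micro_range(curves["SDO"])
    if "RFI" in curves:
        offset = micro_range(curves["RFI"])
    tau = np.nan
    if washout_amplitudes is not None:
        mfit = macro_offset_tau(washout_amplitudes)
        tau = mfit.tau_s
        flags.extend(mfit.flags)

    summ = CompoundSummary(
        measurement_id=measurement_id,
        compound=compound,
        K_R=aff.K_R,
        K_I=aff.K_I,
        K_app=aff.K_app,
        h=h,
        ratio=aff.ratio,
        ic50_by_pulse=fits_by_pulse,
        nh_by_pulse=nh_by_pulse,
        tau_macro_off_s=tau,
        micro_onset=onset,
        micro_offset=offset,
        flags=tuple(flags),
    )
    return summ, curves


def _geo(values: np.ndarray) -> tuple[float, float]:
    logs = np.log(values)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if len(logs) > 1 else np.nan
    return gm, gsd


@dataclass
class GroupSummary:
    n: int
    scalars: pd.DataFrame        # index: quantity; geo_mean, geo_sd, mean, sem
    ratio_of_means: float
    eip_geomean: Optional[dict[str, pd.DataFrame]] = None


def group_summary(
    summaries: Sequence[CompoundSummary],
    curves_by_measurement: Optional[Sequence[dict[str, EIPCurve]]] = None,
) -> GroupSummary:
    """Geometric-mean (and arithmetic) summaries across measurements.

    The state-dependence ratio is reported both as the mean of per-measurement
    K_R/K_I ratios and as the ratio of mean K_R to mean K_I.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries given")
    rows = {}
    for name, getter in (
        ("K_R_uM", lambda s: s.K_R),
        ("K_I_uM", lambda s: s.K_I),
        ("K_app_uM", lambda s: s.K_app),
        ("K_R_over_K_I", lambda s: s.ratio),
    ):
        vals = np.array([getter(s) for s in summaries], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows[name] = (np.nan, np.nan, np.nan, np.nan)
            continue
        gm, gsd = _geo(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows[name] = (gm, gsd, float(vals.mean()), sem)
    scalars = pd.DataFrame(
        rows, index=["geo_mean", "geo_sd", "mean", "sem"]
    ).T
    kr = scalars.loc["K_R_uM", "geo_mean"]
    ki = scalars.loc["K_I_uM", "geo_mean"]
    rom = float(kr / ki) if np.isfinite(kr) and np.isfinite(ki) and ki > 0 else np.nan

    eip_geo = None
    if curves_by_measurement:
        eip_geo = {}
        for section in ("SDO", "RFI", "SSI"):
            per_x: dict[float, list[float]] = {}
            for curves in curves_by_measurement:
                if section not in curves:
                    continue
                for r in curves[section].points.itertuples():
                    per_x.setdefault(float(r.x), []).append(float(r.ic50))
            if per_x:
                recs = []
                for x in sorted(per_x):
                    gm, gsd = _geo(np.array(per_x[x]))
                    recs.append((x, gm, gsd, len(per_x[x])))
                eip_geo[section] = pd.DataFrame(
                    recs, columns=["x", "ic50_geo_mean", "ic50_geo_sd", "n"]
                )
    return GroupSummary(
        n=len(summaries), scalars=scalars, ratio_of_means=rom, eip_geomean=eip_geo
    )


# ---------------------------------------------------------------------------
# EIP over a firing pattern
# ---------------------------------------------------------------------------

@dataclass
class EIPTimecourse:
    """Piecewise EIP(t) built from SDO/RFI curves and spike events."""

    times_ms: np.ndarray
    ic50: np.ndarray
    events: tuple[tuple[float, str], ...]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "ic50_uM": self.ic50})


def _loglog_interp(curve: EIPCurve):
    lx, ly = np.log(curve.x), np.log(curve.ic50)

    def f(dt: np.ndarray) -> np.ndarray:
        dt = np.asarray(dt, dtype=float)
        out = np.empty_like(dt)
        small = dt <= curve.x[0]
        big = dt >= curve.x[-1]
        mid = ~(small | big)
        out[small] = ly[0]
        out[big] = ly[-1]
        out[mid] = np.interp(np.log(dt[mid]), lx, ly)
        return np.exp(out)

    return f


def overlay_eip(
    sdo_curve: EIPCurve,
    rfi_curve: EIPCurve,
    spike_times_ms: Sequence[float],
    repolarization_times_ms: Sequence[float],
    dt_ms: float = 0.5,
    t_end_ms: Optional[float] = None,
) -> EIPTimecourse:
    """EIP time course over a firing pattern.

    After each action-potential upstroke the potency follows the SDO curve
    (clock restarted at the upstroke: depolarization triggers micro-onset);
    after each repolarization it follows the RFI curve (hyperpolarization
    triggers micro-offset).  Interpolation is linear in log time / log IC50,
    clamped at the curve ends.
    """
    ups = [(float(t), "upstroke") for t in spike_times_ms]
    reps = [(float(t), "repolarization") for t in repolarization_times_ms]
    events = sorted(ups + reps)
    if not ups:
        raise ValueError("at least one upstroke is required")
    times = [t for t, _ in events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("event times must be strictly increasing (no overlaps)")
    kinds = [k for _, k in events]
    if kinds[0] != "upstroke":
        raise ValueError("the first event must be an upstroke")
    for a, b in zip(kinds, kinds[1:]):
        if a == b:
            raise ValueError("upstrokes and repolarizations must alternate")

    f_sdo = _loglog_interp(sdo_curve)
    f_rfi = _loglog_interp(rfi_curve)
    if t_end_ms is None:
        t_end_ms = times[-1] + float(rfi_curve.x[-1])
    ts = np.arange(times[0], t_end_ms, dt_ms)
    out = np.empty_like(ts)
    ev_times = np.array(times)
    for i, t in enumerate(ts):
        j = int(np.searchsorted(ev_times, t, side="right")) - 1
        t0, kind = events[j]
        dt = max(t - t0, 1e-9)
        out[i] = f_sdo(np.array([dt]))[0] if kind == "upstroke" else \
            f_rfi(np.array([dt]))[0]
    return EIPTimecourse(times_ms=ts, ic50=out, events=tuple(events))
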