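"""Effective inhibitor potency (EIP) analysis.

The core idea: within a dynamic voltage protocol a compound's potency is not a
single number.  Each of the 17 test pulses probes the channel population in a
different conformational mixture, so each pulse has its own
concentration-inhibition relationship.  Fitting the Hill equation

    Inh(cc) = cc^nH / (cc^nH + IC50^nH)

per pulse yields a per-pulse IC50 — the effective inhibitor potency — which,
plotted against conditioning duration (SDO), interpulse gap (RFI) or holding
potential (SSI), traces the millisecond-scale onset and offset of drug effect
("micro-dynamics").  The per-pulse IC50 fluctuates between the resting-state
and inactivated-state dissociation constants K_R and K_I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocol import VoltageProtocol, condition_of

__all__ = [
    "HillFitResult",
    "EIPCurve",
    "hill_inhibition",
    "make_ratio_table",
    "fit_hill",
    "build_eip_curves",
]

NH_BOUNDS = (0.3, 4.0)

FLAG_OK = "ok"
FLAG_EXTRAPOLATED = "extrapolated"
FLAG_CLIPPED = "clipped_ratios"
FLAG_BOUND = "at_bound"


def hill_inhibition(cc: np.ndarray, ic50: float, n_h: float) -> np.ndarray:
    """Hill equation for the inhibited fraction at concentration(s) ``cc``."""
    cc = np.asarray(cc, dtype=float)
    return 1.0 / (1.0 + (ic50 / cc) ** n_h)


def make_ratio_table(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Drug/control peak-amplitude ratios per (pulse, concentration).

    ``amplitudes`` must be a phase-annotated amplitude table (see
    :func:`eipkit.traces.annotate_phases`).  For each application the mean
    absolute peak over the tagged drug window is divided by the mean absolute
    peak over that application's own pre-application control window.

    Returns a table with columns ``pulse_index, conc_uM, ratio,
    n_sweeps_averaged``.
    """
    if "phase" not in amplitudes.columns:
        raise ValueError("amplitude table has no 'phase' column; run annotate_phases")
    apps = sorted(a for a in amplitudes["application"].unique() if a > 0)
    if not apps:
        raise ValueError("no tagged applications in the amplitude table")
    rows = []
    for k in apps:
        ctrl = amplitudes[amplitudes["phase"] == f"control_{k}"]
        drug = amplitudes[amplitudes["phase"] == f"drug_{k}"]
        if ctrl.empty or drug.empty:
            raise ValueError(f"application {k} lacks control or drug sweeps")
        conc = float(drug["conc_applied_uM"].iloc[0])
        cm = ctrl.groupby("pulse_index")["amplitude_nA"].apply(
            lambda a: np.abs(a).mean()
        )
        dm = drug.groupby("pulse_index")["amplitude_nA"].apply(
            lambda a: np.abs(a).mean()
        )
        n_avg = drug.groupby("pulse_index").size()
        for p in cm.index:
            if cm[p] == 0:
                raise ValueError(
                    f"control mean amplitude is zero at pulse #{p} "
                    f"(application {k}); ratio undefined"
                )
            rows.append((int(p), conc, float(dm[p] / cm[p]), int(n_avg[p])))
    return pd.DataFrame(
        rows, columns=["pulse_index", "conc_uM", "ratio", "n_sweeps_averaged"]
    )


@dataclass
class HillFitResult:
    """Per-pulse concentration-inhibition fit."""

    ic50: float
    n_h: float
    ic50_se: float = np.nan
    nh_se: float = np.nan
    rss: float = np.nan
    pulse_index: Optional[int] = None
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return FLAG_EXTRAPOLATED not in self.flags

    def predict(self, cc: np.ndarray) -> np.ndarray:
        return hill_inhibition(cc, self.ic50, self.n_h)


def _init_log_ic50(logc: np.ndarray, inh: np.ndarray) -> float:
    """Initial log10 IC50: log-interpolate the concentration at Inh = 0.5."""
    order = np.argsort(logc)
    lc, y = logc[order], inh[order]
    for i in range(len(y) - 1):
        lo, hi = sorted((y[i], y[i + 1]))
        if lo <= 0.5 <= hi and y[i] != y[i + 1]:
            f = (0.5 - y[i]) / (y[i + 1] - y[i])
            return float(lc[i] + f * (lc[i + 1] - lc[i]))
    # not bracketed: extrapolate from the most-inhibited point assuming nH = 1
    top = np.argmax(y)
    y_top = min(max(y[top], 1e-3), 1.0 - 1e-3)
    return float(lc[top] + np.log10(1.0 / y_top - 1.0))


def fit_hill(
    concs: Sequence[float],
    inhibitions: Sequence[float],
    pulse_index: Optional[int] = None,
    weights: Optional[Sequence[float]] = None,
) -> HillFitResult:
    """Least-squares Hill fit of inhibition vs log concentration.

    Inhibitions are clipped to [0, 1] before fitting (ratios slightly above 1
    from noise count as zero inhibition).  The fit is performed in
    ``(log10 IC50, nH)`` space with bounds ``nH in [0.3, 4]`` and ``IC50 in
    [min(cc)/100, max(cc)*100]``; unweighted by default.  A fit whose data do
    not bracket half-inhibition (all points < 0.05 or > 0.95) is flagged
    ``extrapolated`` rather than rejected.
    """
    cc = np.asarray(concs, dtype=float)
    inh_raw = np.asarray(inhibitions, dtype=float)
    if cc.shape != inh_raw.shape:
        raise ValueError("concs and inhibitions differ in length")
    if len(np.unique(cc)) < 3:
        raise ValueError("at least 3 distinct concentrations are required")
    if np.any(cc <= 0):
        raise ValueError("concentrations must be > 0")
    order = np.argsort(cc)
    cc, inh_raw = cc[order], inh_raw[order]
    sigma = None
    if weights is not None:
        wts = np.asarray(weights, dtype=float)[order]
        sigma = 1.0 / np.sqrt(wts)

    flags: list[str] = []
    if np.any(inh_raw < 0) or np.any(inh_raw > 1):
        flags.append(FLAG_CLIPPED)
    inh = np.clip(inh_raw, 0.0, 1.0)
    if np.all(inh < 0.05):
        flags.append(FLAG_EXTRAPOLATED)
    elif np.all(inh > 0.95):
        flags.append(FLAG_EXTRAPOLATED)

    logc = np.log10(cc)
    lb, ub = np.log10(cc.min() / 100.0), np.log10(cc.max() * 100.0)
    p0 = [np.clip(_init_log_ic50(logc, inh), lb, ub), 1.0]

    def model(lc: np.ndarray, log_ic50: float, n_h: float) -> np.ndarray:
        return 1.0 / (1.0 + 10.0 ** (n_h * (log_ic50 - lc)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            model, logc, inh, p0=p0, sigma=sigma,
            bounds=([lb, NH_BOUNDS[0]], [ub, NH_BOUNDS[1]]),
            maxfev=10000,
        )
    log_ic50, n_h = popt
    resid = inh - model(logc, *popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    ic50 = 10.0 ** log_ic50
    tol = 1e-6
    if (log_ic50 - lb < tol or ub - log_ic50 < tol
            or n_h - NH_BOUNDS[0] < tol or NH_BOUNDS[1] - n_h < tol):
        flags.append(FLAG_BOUND)
    return HillFitResult(
        ic50=float(ic50),
        n_h=float(n_h),
        ic50_se=float(np.log(10) * ic50 * perr[0]),
        nh_se=float(perr[1]),
        rss=float(resid @ resid),
        pulse_index=pulse_index,
        flags=tuple(flags),
    )


@dataclass
class EIPCurve:
    """IC50 (effective inhibitor potency) vs a protocol condition axis."""

    section: str
    points: pd.DataFrame  # pulse_index, x, ic50, ic50_se, n_h, nh_se, flag
    measurement_id: str = ""
    x_unit: str = "ms"

    def __post_init__(self) -> None:
        x = self.points["x"].to_numpy()
        if np.any(np.diff(x) <= 0):
            raise ValueError(f"{self.section} x-values must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.points["x"].to_numpy(dtype=float)

    @property
    def ic50(self) -> np.ndarray:
        return self.points["ic50"].to_numpy(dtype=float)

    def ic50_of_pulse(self, pulse_index: int) -> float:
        row = self.points[self.points["pulse_index"] == pulse_index]
        if row.empty:
            raise KeyError(f"pulse #{pulse_index} not in {self.section} curve")
        return float(row["ic50"].iloc[0])


def build_eip_curves(
    ratio_table: pd.DataFrame,
    protocol: VoltageProtocol,
    measurement_id: str = "",
) -> dict[str, EIPCurve]:
    """Per-pulse Hill fits arranged into SDO, RFI and SSI EIP curves.

    Fits one Hill curve per pulse across all concentrations in the ratio
    table; pulses belonging to several sections appear in each.  Flagged
    (extrapolated / at-bound) fits are kept and carried with a quality flag.
    Also returns every per-pulse fit via the curves' ``points``.
    """
    concs = np.sort(ratio_table["conc_uM"].unique())
    if len(concs) < 3:
        raise ValueError(
            f"at least 3 concentrations required to build EIP curves, got {len(concs)}"
        )
    fits: dict[int, HillFitResult] = {}
    for p, grp in ratio_table.groupby("pulse_index"):
        grp = grp.sort_values("conc_uM")
        inh = 1.0 - grp["ratio"].to_numpy()
        fits[int(p)] = fit_hill(grp["conc_uM"].to_numpy(), inh, pulse_index=int(p))

    x_units = {"SDO": "ms", "RFI": "ms", "SSI": "mV"}
    curves: dict[str, EIPCurve] = {}
    for section in ("SDO", "RFI", "SSI"):
        rows = []
        for p, fit in fits.items():
            cond = condition_of(protocol, p)
            if section not in cond.sections:
                continue
            rows.append(
                {
                    "pulse_index": p,
                    "x": cond.x_value(section),
                    "ic50": fit.ic50,
                    "ic50_se": fit.ic50_se,
                    "n_h": fit.n_h,
                    "nh_se": fit.nh_se,
                    "flag": ";".join(fit.flags) or FLAG_OK,
                }
            )
        if not rows:
            continue
        pts = pd.DataFrame(rows).sort_values("x").reset_index(drop=True)
        curves[section] = EIPCurve(
            section=section, points=pts, measurement_id=measurement_id,
            x_unit=x_units[section],
        )
    return curves
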