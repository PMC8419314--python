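# Methods

## The channel + drug model

The simulator is a continuous-time Markov chain.  The drug-free channel is a
four-state gating scheme

    C1 ⇌ C2 ⇌ O ⇌ I,   I → C1 (recovery)

with rates r(V) = A·exp(V/k_V) (A in 1/ms, k_V in mV; k_V = ∞ gives a
voltage-independent rate).  The bundled "generic fast NaV" parameter set is
an engineering default, not a fit to any recorded channel.  It is tuned to
four design goals:

* activation and fast inactivation complete within ~5 ms at −10 mV
  (O→I rate 1.5 ms⁻¹, activation steps 8·exp(V/36) ms⁻¹);
* recovery from inactivation at −130 mV with τ ≈ 3.4 ms
  (I→C1 rate 0.067·exp(−V/87) ms⁻¹);
* roughly 40% of the population inactivated at steady state at −70 mV, so
  the inactivated-fraction correction h is well exercised;
* resting inactivation < 0.1% at −130 mV.  This last point matters more
  than it looks: the rested-pulse IC50 approximates K_R only while the
  rested population is essentially free of high-affinity (inactivated)
  states — a 1% inactivated contaminant already halves the apparent K_R
  of a compound with K_R/K_I = 100.

A bound inhibitor mirrors the gating space (8 states total).  Binding from
state X proceeds at access(X)·k_on·cc and unbinding at k_on·K_R from
resting-class states (C1, C2, O by default) or k_on·K_I from
inactivated-class states.  Gating rates in the bound layer are rescaled so
that every unbound↔bound 4-cycle satisfies microscopic reversibility:
writing w(X) = K(X)/access(X), the bound rate X*→Y* is the unbound rate
times min(w(X)/w(Y), 1) under the default **"recovery" closure** — i.e. the
whole K_R/K_I factor lands on transitions leaving the inactivated class, so
bound channels recover from inactivation K_R/K_I-fold more slowly.  This
reproduces the drug-induced delay of recovery from inactivation.  The
alternative "onset" closure (bound channels inactivate faster,
max(w(X)/w(Y), 1)) is implemented but not default: it turns open-state
binding into a nearly irreversible sink on the sub-millisecond path to the
current peak, which grossly distorts the rested-pulse IC50 for
fast-binding compounds.

Bound channels do not conduct by default (`bound_open_conductance = 0`);
a nonzero value models modulated-receptor scenarios where bound open
channels retain partial conductance.

### Timescale consequences of the closure

With the recovery closure, the observable micro-offset after a
repolarization is governed by unbinding from the bound-inactivated pool,
rate ≈ k_on·K_I (+ the slowed bound recovery, usually negligible).  A
compound specified by "micro-offset τ ≈ 3 ms" therefore needs a *fast*
association rate: k_on = 1/(3·K_I).  At positive bath concentration the
escape is prolonged by rebinding: a channel that unbinds while still
inactivated rebinds at k_on·cc before it manages to recover (rate ~0.3
ms⁻¹), so the effective escape time grows roughly by the factor
(1 + k_on·cc/k_recovery).  `bound_escape_tau_ms` computes this effective
escape time directly from the generator; the measured RFI micro-offset
window spans the concentration-dependent range of these escape times, not a
single exponential — which is also why micro-dynamics are reported as time
*ranges* rather than fitted time constants.

## The 17-pulse protocol

One 1000 ms sweep (1 Hz) holds at −130 mV and pulses to −10 mV:

* **#1** — rested baseline at the sweep start, 498 ms after the last
  depolarization of the previous sweep (it doubles as the longest
  recovery-from-inactivation point);
* **#2–#5 (SDO)** — independent conditioning depolarizations of 2.5, 7.5,
  22.5 and 67.5 ms, each followed by a 2.5 ms hyperpolarizing gap and a 5 ms
  test pulse, with a 20 ms inter-unit recovery interval;
* **#6–#12 (RFI)** — 5 ms test pulses separated by hyperpolarizing gaps of
  64, 1, 2, 4, 8, 16 and 32 ms (in protocol order; the gap→pulse assignment
  is a config field);
* **#12–#17 (SSI)** — test pulses from holding levels −130, −110, −100,
  −90, −80, −70 mV after a 20 ms per-level equilibration.

All durations and voltages are configurable; the defaults make the segment
durations sum to exactly the sweep period, so the physical interval before
pulse #1 equals its nominal 498 ms label.  The 20 ms SSI equilibration (and
the 20 ms SDO recovery) are what the 1 s sweep budget allows; 20 ms is ~2.3
availability time constants at −70 mV, so the SSI section is an approximate,
not exact, steady state — the same compromise the measurement itself makes.
Segment boundaries are half-open [t_start, t_end).

## Simulation and peak readout

Within a segment the voltage (hence the generator Q) is constant and
occupancy propagates by matrix exponential; inside test pulses the occupancy
course is evaluated on a 0.01 ms grid (eigendecomposition when the
generator is well conditioned, step-propagator fallback otherwise).  The
reported peak is the extremum of open-state occupancy *relative to the
instantaneous pre-pulse level*, matching the trace-processing convention
(the linear-baseline leak subtraction also removes the window current at
depolarized holdings).  Inward current is negative; conductance_scale maps
open probability to nA (default 10 nA at full opening, i.e. control peaks
of ~5 nA from rest).

Perfusion: the bath concentration relaxes exponentially toward each schedule
block's target with the compound's perfusion_tau_s.  Measurement noise is
multiplicative Gaussian on each per-pulse peak (default sd 2%), with an
optional linear rundown; one integer seed drives everything, and replicate
"ensembles" are modeled as independent noise draws on the same underlying
peaks.  Cell-to-cell variability in channel count or gating is *not*
modeled, so passing recovery tests here demonstrates correctness of the
analysis chain under measurement noise, not robustness to biological
heterogeneity.

## Analysis chain

1. **Peaks** (`traces`): per-pulse extrema after 0.2 ms artifact blanking
   and linear-baseline leak subtraction fitted to the quiet pre-pulse
   window (the post-pulse window for a pulse at the sweep start).  Real
   acquisition systems' P/N subtraction and filtering are assumed done
   upstream.
2. **Phases** (`annotate_phases`): the analysis uses only the last 5 s of
   drug-free recording before each application (its own control) and the
   last 5 s of each application.
3. **Ratios** (`make_ratio_table`): mean |drug| / mean |control| per
   (pulse, concentration); ratios can exceed 1 under noise and are kept in
   the table but clipped to zero inhibition for fitting.
4. **Hill fits** (`fit_hill`): unweighted least squares on inhibition vs
   log concentration, parameters (log10 IC50, n_H), bounds n_H ∈ [0.3, 4]
   and IC50 ∈ [min cc/100, max cc·100], initialized by log-interpolating
   the half-inhibition concentration.  Curves whose data never cross 5–95%
   inhibition are flagged `extrapolated`, not discarded.  n_H is fitted
   per pulse independently.
5. **EIP curves** (`build_eip_curves`): IC50 against conditioning duration
   (SDO), preceding gap (RFI) or holding level (SSI); pulses in two
   sections appear in both.
6. **Descriptors** (`summary`): K_R = IC50(#1); h = 1 − |#17|/|#1| over the
   pre-application control window; K_I = h/(1/K_app − (1−h)/K_R) with
   K_app = IC50(#17).  The available fraction weights K_R in the mixture —
   in the limit of complete inactivation K_app → K_I, and with no
   inactivation K_I is unidentifiable (an error).  Micro ranges: the times
   at which the monotonized log-IC50 progress along a curve crosses 10% and
   90% of its span, log-interpolated, plus a copy snapped outward to the
   reporting grid {0.1, 1, 2, 4, 10, 100, 500, 1000} ms; curves with less
   than 1.5-fold total span are flagged flat (no detectable
   micro-dynamics).  Macro-offset: single-exponential fit of the washout
   recovery of |peak #17|.  Because amplitude is a saturating function of
   concentration, the fitted washout τ approaches the perfusion τ only when
   the washed-out concentration is at or below K_app; at several-fold
   higher concentrations it reads up to ~2× slower.
7. **Group statistics**: geometric mean and geometric SD per scalar and per
   EIP point (plus arithmetic mean ± SEM); the state-dependence ratio is
   reported both as the mean of per-measurement ratios and as the ratio of
   mean K_R to mean K_I.  The EIP-change test is a Friedman rank test on
   log IC50 with measurements as blocks; the asymptotic p-value uses the
   Iman–Davenport F refinement (the plain chi-square approximation is off
   by up to ~0.04 at n = 6 blocks), and a within-block permutation variant
   of the same statistic serves as the small-sample reference.  Power for
   the n-per-group two-sample design uses the noncentral-t distribution.
8. **QC** (`qc_filter`): ensembles are excluded for control amplitude
   < 2 nA, mean seal resistance < 80 MΩ, > 20% gradual seal loss, or a
   sudden amplitude drop with concurrent seal drop; survivors are ranked by
   (seal resistance, stability) and the best six kept by default.

## Numerical choices and degenerate inputs

* Occupancy vectors are validated (nonnegative, sum 1 within 1e−8), tiny
  negative round-off from the matrix exponential is clipped, and
  conservation is enforced to 1e−9 across every segment.
* The eigendecomposition path for fine-grid courses falls back to repeated
  one-step propagation when the eigenvector matrix condition number exceeds
  1e10.
* Zero concentration exactly zeroes all binding rates; an unbound
  population can never acquire bound occupancy.
* A zero control mean at any pulse aborts ratio construction with the pulse
  named; non-recovering washout series and inconsistent affinity estimates
  (K_app > what any positive K_I can produce) return flagged results rather
  than raising.
* Access factors of exactly 0 are rejected in the closure (the
  thermodynamic weight K/access diverges); model full inaccessibility by
  affinity class instead.

## Known limitations

* Membrane partitioning and protonation are lumped into k_on; compounds for
  which these are rate-limiting are represented only effectively.
* The generic channel recovers from inactivation with τ ≈ 3.4 ms at
  −130 mV; phenomena that hinge on sub-millisecond recovery (the full
  extent of onset under-detection for extremely fast compounds) are
  reproduced in direction but compressed in magnitude.
* Single-channel stochasticity, temperature, series-resistance and
  capacitance artifacts are out of scope; traces are deterministic
  ensemble currents plus peak-level noise.
* The 1–2 ms RFI points sit slightly below the monotone EIP trend for any
  compound because channel availability itself is still recovering there;
  tests assert strict monotonicity only beyond the channel's recovery time.

## Default problem sizes

Simulated experiments in the tests and the acceptance script use schedules
of 15 control + 20 drug sweeps per application (plus a 40-sweep terminal
washout) at one sweep per second, 3–4 concentrations, and 6 replicate
ensembles — a compact instance of the experimental design whose windows
(5 s control / 5 s drug) and replicate count match the analysis defaults.
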