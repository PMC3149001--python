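# Methods

## Scope and model form

`mlcpath` simulates myosin light chain (MLC) activation in endothelial
cells downstream of three permeability mediators — thrombin, histamine and
VEGF — as a deterministic mass-action reaction network (~80 reactions,
~65 species). The terminal observable is the percentage of the MLC pool in
a phosphorylated state,

    MLC activation (%) = 100 * ([pMLC] + [ppMLC]) / [MLC]_total ,

with the di-phosphorylated form `ppMLC` exposed separately as the
sensitivity-analysis output. Concentrations are micromolar and time is in
seconds internally; minutes appear only in reports. The model is a curated
mechanistic reconstruction, not a literal transcription of any published
reaction table: mechanisms with no quantitative intermediate-level
constraints are lumped (see below).

## Cascade architecture

* **Thrombin / PAR-1.** Thrombin engages PAR-1 as a tight, effectively
  irreversible complex (the proteolytically activated receptor cannot
  revert); the active receptor is internalized first-order with slow
  recycling. The dose therefore sets the size of the activated pool —
  receptor-limited at 0.05 uM, ligand-limited at nanomolar doses — which
  is what separates the strong transient high-dose response from the weak
  sustained low-dose one. Active PAR-1 drives Gq (PLCβ) and G12/13
  (RhoGEF → Rho).
* **Calcium.** PLCβ (Gq) and PLCγ (VEGFR2) produce IP3 and DAG. IP3 gates
  Ca²⁺ release from a finite internal store; SERCA-type re-uptake plus
  plasma-membrane extrusion against a clamped extracellular reservoir
  (boundary species) terminate the transient by store depletion even under
  sustained IP3. A small receptor-operated entry term (flux proportional
  to active Gq) produces the mild plateau above resting Ca²⁺ that sustains
  basal MLCK flux during prolonged stimulation.
* **CaM/MLCK.** Cooperative Ca²⁺–calmodulin loading is lumped into two
  sequential 2-Ca²⁺ binding steps; Ca₄CaM–MLCK is the active kinase. ERK
  phosphorylates MLCK into a higher-activity form that is modelled as
  active at resting Ca²⁺ — the lumped representation of the increased
  Ca²⁺ sensitivity of phospho-MLCK, and the carrier of the VEGF route.
* **Rho/ROCK.** GEF loading and first-order GAP hydrolysis cycle Rho.
  ROCK is auto-inhibited (folded) until Rho-GTP binds and opens it; the
  open conformation is activated by Rho GTPase or, independently, by PKG.
  Active ROCK phosphorylates MLC directly and phosphorylates the
  myosin-phosphatase targeting subunit (MYPT1), inhibiting MYCP.
* **MYCP/CPI-17.** MYCP dephosphorylates pMLC/ppMLC. DAG-activated PKC
  phosphorylates CPI-17; phospho-CPI-17 binds MYCP stoichiometrically as
  an inhibited complex. Because the complex shields phospho-CPI-17 from
  dephosphorylation, the binding equilibrium (not the phosphorylation
  balance alone) sets the residual phosphatase activity; its dissociation
  constant is one of the most sensitive constants in the model.
* **VEGF/ERK.** VEGF–VEGFR2 binding forms an active complex that is
  internalized first-order (the source of the transient ERK peak). The
  Ras → Raf → MEK → ERK cascade uses distributive double phosphorylation
  at the MEK and ERK levels, deliberately run at low fractional activation
  where the double-phosphorylation ultrasensitivity (local log-log gain up
  to 2 per level) is maximal — this is what lets a 20% VEGFR2 increase
  produce a ~15% main-peak gain despite saturation elsewhere.
* **NO/PKG.** Receptor-primed eNOS (histamine or VEGF) must also bind
  Ca₄CaM to produce NO; NO → sGC → cGMP → PKG runs sub-saturated so PKG
  activity tracks the decline of receptor priming instead of latching on.
  PKG activates Raf weakly (the NO→ERK link) and open ROCK strongly (the
  synergy route).

**Synergy mechanism.** Under histamine or VEGF alone, ROCK stays folded
(no Rho-GTP) and PKG is idle as a contraction driver. Under low-dose
thrombin alone, ROCK opens but is only weakly activated by Rho. In
combination, thrombin-supplied Rho-GTP opens ROCK and partner-supplied PKG
activates it — a structural AND-gate that produces the super-additive
10–50 min activation window. The window closes when PKG decays (receptor
internalization/desensitization upstream) and MYCP recovers.

## Stimulus configuration

A `StimulusConfig` fully determines one in-silico experiment: mediator
doses (uM), over-expression multipliers for PAR-1, Rho GTPase, ROCK, VEGF,
VEGFR2 and CPI-17 (pool scalings; the VEGF multiplier scales the dose),
cascade on/off switches (`ca_dependent`, `rock_dependent`,
`cpi17_dependent`, `no_dependent`, `ras_erk` — switching off zeroes the
rate constants of tagged reactions), and per-species initial-concentration
overrides. Ablations are expressed as cascade labels because the
mechanistic claims they test are stated per cascade, not per reaction
index. Mediators are ordinary depleting species; the boundary
(clamped-concentration) flag exists but is used only for the extracellular
Ca²⁺ reservoir.

Default doses follow the study conditions: thrombin 0.05 uM and VEGF
0.02 uM for single-mediator validation; 0.0015 uM thrombin + 0.0050 uM
histamine and 0.002 uM thrombin + 0.010 uM VEGF for the low-dose
combination analyses; histamine defaults to 0.005 uM (the combination
dose; no separate single-dose value is stated anywhere, so the package
keeps it as a config default rather than a constant).

## Baseline and pre-equilibration

Pool sizes sit inside their stated physiological ranges (PAR-1 0.01 of
0.002–0.02 uM; ROCK 0.15 of 0.06–0.3; VEGFR2 0.012 of 0.012–0.072;
CPI-17 0.08 uM). Before every run the unstimulated cell is relaxed to its
steady state (LSODA, 3e5 s, rtol 1e-10) and that state becomes the initial
condition; doses are then added. This makes the mediator-zero
configuration a fixed point to solver tolerance and the basal activation
(< 2%) an emergent property rather than an input.

## Numerics

The reference solver is the adaptive Dormand–Prince 4(5) pair with
absolute tolerance 1e-6 and relative tolerance 1e-3, sampled on a fixed
1 s output grid over a 100 min default horizon; a failed explicit run
falls back to LSODA with the switch logged. The two solvers agree on MLC
activation to < 0.01 percentage points here, so property tests that need
many integrations use LSODA for speed while the validation features are
checked on the default pair. Peaks are topographic-prominence maxima
(default threshold 2 percentage points; endpoints count only when the
series decreases away from them, ties break earliest). One derived quantity needs more than the default accuracy: the cytosolic
Ca²⁺ maximum sits on a flat top, so locating its time on the 1 s grid uses
a refined-tolerance integration (rtol 1e-8) of the first ten minutes —
at default tolerances the argmax wanders several seconds within the
solver-error band. Binned areas are
trapezoidal integrals of the activation *fraction* over 10-min bins
(fraction·min), so a bin-mean activation of 59% gives area 5.9; net
synergy gain is the combination area minus the sum of the two
single-mediator areas, exactly.

## Parameter provenance and calibration

Every rate constant carries a provenance class: `published_model`
(order-of-magnitude values carried from prior ODE models of the
constituent cascades), `analogous_pair` (seeded from kinetically analogous
protein pairs, e.g. the Rho cycle from the Ras cycle), or `fitted`. Only
the fitted class — a documented minority — is free during calibration;
all classes move inside a ten-fold box around their seed, symmetric in
log space.

Calibration is bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, `trf`) on log-parameters against the
printed validation features: activation percentages at stated times, peak
times, binned areas and net synergy gains, each standardized by its
experimental tolerance. Fitting proceeds in rounds restarting from the
previous optimum until the standardized R² exceeds 0.6 (the shipped set
reaches ≈0.9) or an iteration cap; the one shipped parameter table
(`params/calibrated.yaml`) must satisfy the whole suite simultaneously —
there is no per-figure re-tuning, and the acceptance tests enforce this.

Two printed tables are mutually inconsistent about the low-dose
thrombin-alone time course (one shows it sustained to 80 min, the other
decaying after 30 min at a nearly identical dose); the calibration treats
the decaying shape as authoritative because it follows from receptor
internalization, and fits the combination curves and net gains — the
quantities the synergy analysis actually uses — rather than every
single-mediator bin. One printed single-mediator bin value that is
inconsistent with its neighbours by two orders of magnitude is treated as
a typographical error and excluded.

## Sensitivity analysis

Local sensitivities are computed by the direct route — perturb one
constant, re-integrate, differentiate the output — with two engines: a
complex-step derivative (relative step 1e-20 pushed through the explicit
integrator in complex arithmetic; no cancellation error) and central
finite differences as the documented fallback and the default for
whole-table ranking (5% symmetric step with rtol 1e-8, where derivative
truncation stays well below the step response). Sensitivities are
normalized (d ln output / d ln parameter); the per-parameter summary is
the maximum absolute normalized sensitivity over the horizon, and the
sensitive/insensitive threshold is 10% of the largest summary (a declared
convention; no sharper definition is stated anywhere). Reactions sharing
one named constant are perturbed together. On the calibrated model the
sensitive set is a small minority concentrated in the CPI-17/phosphatase,
PKC/DAG and Rho/ROCK constants, matching the robustness structure the
sensitivity analysis is meant to demonstrate.

## Reproduction status

With the shipped parameter table the headline quantities — the thrombin
activation levels at 30 and 60 min, the 38 s calcium peak, the first-peak
time, the VEGF main-peak and ERK-peak times, the 15% VEGFR2
over-expression response, the combination maxima and the 20-30 min net
synergy gains of both mediator pairs — are reproduced at their printed
tolerances. Of the wider 36-feature suite, 24 sit within one experimental
tolerance and all within 3.4; the misses are concentrated where the two
printed combination tables contradict each other about the low-dose
thrombin time course, plus the 30-second rise value (which trades directly
against the calcium-peak and first-peak times through the shared transient
shape) and a late phase that tops out near 20 min rather than 30. The
`validate` command prints the full per-feature report.

Two behaviors deviate knowingly from the source account. First, ablating
the Ca2+-dependent route halves (rather than barely touches) the sustained
thrombin phase: in this lumping the basal Ca2+/CaM-MLCK flux — the same
term that carries the histamine tail — contributes to the late balance,
and the cascade switch removes it together with the transient. Second,
local sensitivity analysis marks about a third of the constants as
sensitive at the 10%-of-maximum threshold instead of the expected small
minority: a compact curated network (87 constants in place of several
hundred) has little of the redundancy that renders most parameters of the
original inert, so each constant carries measurable function. The
companion structural property — CPI-17-, PKC- and ROCK-related constants
inside the sensitive set — holds.

## What the tests do and do not show

All quantitative checks run against the model's own simulated output under
the stated study conditions; no external time-series data ship with the
package. Passing the feature suite therefore shows that one parameter set
reproduces the printed behaviors simultaneously — not that the constants
are individually identified (the recovery harness shows identifiability
only for well-constrained constants), and not that the model extrapolates
outside the calibrated dose ranges. Known limitations: no junction
mechanics or barrier-resistance prediction downstream of MLC; no PAR-2/3/4
or Flt-1 branches; single well-mixed compartment; the low-dose
thrombin-alone tail follows the decaying variant of the two inconsistent
printed tables (see above); and the histamine single-mediator dose is an
inference, not a printed constant.

## Problem sizes used

Default report grid 1 s over 60–100 min horizons (3,600–6,000 output
points, ~65 state variables); synergy tables use 80 min horizons and
10-min bins; sensitivity ranking uses a 60 min horizon on a 60 s output
grid. These are the spans of the corresponding experiments; all run in
seconds (LSODA) to a few tens of seconds (Dormand–Prince) on one CPU.
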