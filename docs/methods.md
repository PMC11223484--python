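# Methods

## The control problem

Enzymatic PET hydrolysis releases terephthalic acid (TPA, a diacid) and
small amounts of the monoacid intermediate MHET. At 10% solids the total
acid release is of order 1 mol/L of proton equivalents — far beyond what a
100 mM phosphate buffer can absorb — so without base addition the pH falls
out of the enzyme's working range within hours. A pH-stat counteracts this
with dead-zone on–off control: compare the latest reading with
`target ± tolerance` every `cycle_time` seconds and, when the reading is
below the band, deliver one fixed-volume shot of NaOH. The cumulative shot
count, times the set dose volume and titrant concentration, is itself a
progress read-out via the 2 mol NaOH : 1 mol TPA stoichiometry.

## Solution chemistry

The medium state is the vector of total concentrations of the protic
species (phosphate, TPA, MHET), the strong-cation total (Na+), volume and
pKw. pH is the unique root of the charge-balance residual; speciation
follows standard stepwise dissociation. Choices:

- **Equilibrium constants** default to 25 °C ideal-dilute values
  (phosphate pKa 2.15 / 7.21 / 12.33, TPA 3.51 / 4.46, MHET 3.2, pKw
  13.997), all overridable in the config. The reaction runs at 65 °C, but
  temperature corrections of pKa/pKw are deliberately not hard-coded: they
  would imply a precision the rest of the plant model does not have, and
  the controller only ever sees pH relative to its target. Temperature is
  carried as metadata.
- **Activities = concentrations.** No ionic-strength model; its error is
  absorbed into the kinetic calibration.
- Ethylene glycol is pH-inert and tracked only for mass balance; BHET has
  no acidic proton at assay pH and appears only in product accounting.
- The solver brackets on (0, pKw) and uses Brent's method to 1e-10 pH;
  strict monotonicity of the residual guarantees uniqueness. Compositions
  with no root in that interval (≳1 M excess strong acid/base) raise.

At pH 8 the average TPA charge is −(2 − 10^(pKa₂−8)) ≈ −1.99942, i.e. the
"2 NaOH per TPA" rule is exact only to ~1.4 × 10⁻⁴ relative; the package
keeps the conventional factor 2 in the estimator and quantifies the
resulting (tiny, conservative) bias in its tests rather than silently
correcting it.

## Film kinetics

No mechanistic rate law is established for film-scale PET hydrolysis at
these loadings, so the simulator uses the simplest law that reproduces the
observed near-linear-then-plateau base-addition profiles:

    r = k_s · A(t) · [E](t) · a(t)        [mol repeat units / h]

- `A(t)`: slab model. Faces contribute a constant `2 n L W`; edges scale
  with the current thickness inferred from remaining mass. Area drops to
  zero at depletion.
- `[E]`: bulk enzyme in mg/mL; diluted by every dose and withdrawal.
- `a(t) = exp(−k_d t)`: first-order activity decay.
- A fraction `φ_MHET` of released units enters the MHET pool, which
  converts to TPA + EG with first-order rate `k_MHET`; MHET production
  within a step is integrated exactly against the decay, and mass balance
  (`remaining + M·(TPA + MHET + BHET) = initial`) holds to float precision
  at every step.

Defaults (12 mL scenario): `k_s = 7.5e-6 mol cm⁻² h⁻¹ (mg/mL)⁻¹`,
`k_d = 0.01 h⁻¹`, `φ_MHET = 0.10`, `k_MHET = 0.3 h⁻¹`. The rate constant is
calibrated once so the packaged small-scale scenario reaches ≳90%
conversion in 72 h with ~12 mL of 1 M NaOH; it is a packaged default, not a
fitted claim. With a constant release fraction and first-order conversion,
MHET cannot simultaneously be ~10% of products at 24 h *and* fully consumed
by 48 h; the defaults favor the second observation (MHET is a transient
minor intermediate, < 1% of aromatics by 48 h), and both knobs are exposed
for scenarios where MHET accumulates strongly.

The litre-scale config uses the same `k_s` but `k_d = 0.016 h⁻¹`
(constant 400 rpm Rushton agitation is harsher on the enzyme than the
intermittently stirred vials) and a 30 s control cycle (a commercial dosing
module reacts faster than the 90 s user cycle of the small-scale
controller).

## Plant and probe

- Probe: Gaussian read noise (default sd 0.02 pH) then quantization
  (default 0.01 pH). The electrode's 0.1-pH precision figure is kept as a
  separate `accuracy_band` attribute — it motivates the recommended 0.1
  control tolerance but is deliberately not applied to readings, since the
  digital transmitter reports finer than the electrode's stated accuracy.
- Pump: delivered volume `max(0, N(nominal, sd))` with default 40 ± 10 µL,
  the measured spread of small peristaltic pumps. The controller books
  `count × set_dose_volume` exactly (that is what hardware logs contain);
  plant ground truth differs only through this scatter.
- Dosing dilutes every dissolved total and grows the volume; scheduled
  sample withdrawals (off by default) remove dissolved species and enzyme
  proportionally but never solids.
- Temperature is held at the setpoint; thermal dynamics, stirring
  hydrodynamics and CO₂ uptake are out of scope.

## Controller semantics

- The dead zone is **closed**: a reading exactly at `target ± tolerance`
  does not trigger a dose.
- Exactly one fixed dose per due cycle; large excursions are corrected over
  several cycles. Decisions use the latest reading only, unfiltered.
- `cycle_time` (default 90 s) is the single authoritative decision
  interval; readings occur every 30 s regardless.
- The overflow guard halts — latched until an explicit reset — whenever the
  *next* dose would push the cumulative volume past `max_added_volume`.
  Whether a raised budget should resume dosing is ambiguous on hardware; a
  latch is the safe reading.

## Scheduler and log

Discrete-event simulation: kinetics sub-steps (default 10 s), a reading
every `measure_interval` (30 s), control decisions when due, dose delivery
and book-keeping atomic. No real-time sleeping — the package is a
simulator/analyzer, not a hardware daemon. The log CSV
(`time_s,ph_reading,ph_true,dose_count,cumulative_volume_mL,action`) writes
floats with `repr`, so read∘write is exact; `# key: value` comment headers
carry the seed, config digest, titrant concentration and initial PET mass,
making a log self-contained for analysis. Hardware logs lacking `ph_true`
parse with that field absent.

## Analysis conventions

- `conversion_from_base` uses the conventional 2:1 stoichiometry even
  though MHET (one acidic proton) and the TPA protonation tail make it
  slightly conservative; the simulator's ground truth quantifies the bias
  (it is bounded by the un-titrated buffer capacity across the tolerance
  band plus the MHET and speciation deficits, and the base estimate never
  exceeds the product estimate).
- `rolling_mean` is centered with shrinking windows at the edges (default
  50 points); a trailing variant is available by flag.
- `fraction_in_tolerance` counts logged readings in the closed band;
  readings are equispaced, so this equals the fraction of reaction time.
- `parallel_module_budget`: `simultaneous = floor(supply/active)`;
  `total_staggered` is the largest n with `k·active + (n−k)·sleep ≤ supply`
  where `k = min(simultaneous, n)` — a best-effort formalization of
  staggered-read scheduling.

## What the simulator does and does not show

Passing tests demonstrate the control logic, accounting, chemistry and the
internal consistency of the three conversion estimators under a plausible
synthetic plant. They do not validate the kinetic rate law against real
film hydrolysis: real runs show probe drift and fouling, pump-to-pump
systematic volume offsets (30–45 µL), heterogeneous film suspension and
sampling noise, none of which are modelled. In-tolerance percentages from
the simulator (~92%) are therefore not comparable in detail to hardware
values (~79–80% at the small scale); the package claims the qualitative
regime, not those numbers.

## Problem sizes

Default runs simulate 72 h at 10 s kinetics steps and 30 s readings
(8641 log records, ~26 000 kinetic steps); a full scenario takes a couple
of seconds, and the whole test suite — including two full-length scenario
runs and a 100-composition solver-vs-grid-scan cross-check — runs in well
under a minute.
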