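# Methods

## Scope and state space

The package models the information flow from a cytosolic Ca²⁺ time course
("calcium signature") to CAMTA-regulated mRNA in three stages: (i) a
mass-action binding network of Ca²⁺, calmodulin (CaM) and CAMTA under a
clamped Ca²⁺ input; (ii) a delayed Hill-type transcription stage driven by
the fully loaded complex 4Ca²⁺–CaM–CAMTA (`M22X`); (iii) analysis
operations (fold-change amplification, decoding, history, scans,
calibration) built on the first two.

CaM occupancy states form a 3 × 3 × 2 lattice — 0–2 Ca²⁺ on the N-lobe,
0–2 on the C-lobe, CAMTA bound or not — giving 18 CaM species plus free
CAMTA: 19 state variables (canonical order `M00 … M22`, `M00X … M22X`, `X`;
apo-CaM first, free CAMTA last). The 33 reversible reactions are 12 Ca²⁺
steps in the free layer, 12 in the CAMTA-bound layer, and 9 CaM–CAMTA
binding steps.

Ca²⁺ is an externally clamped input, never a state variable: signatures are
measured or constructed quantities and the model does not feed CaM
buffering back onto them. There is correspondingly no Ca²⁺ generation
machinery, no spatial compartmentalization, no CAMTA isoforms, and no
protein layer downstream of mRNA.

## Parameter completion by detailed balance

Measured anchors: per-lobe Ca²⁺ dissociation constants and on-rates
(C-lobe: 10 μM at 4 μM⁻¹s⁻¹, 0.925 μM at 10 μM⁻¹s⁻¹; N-lobe: 25 μM at
100 μM⁻¹s⁻¹, 5 μM at 150 μM⁻¹s⁻¹), the affinity of Ca²⁺-loaded CaM for
CAMTA (1.2 × 10⁻³ μM, on-rate 1 μM⁻¹s⁻¹), and the relative weakness of the
apo-CaM–CAMTA interaction, expressed by a cooperativity factor P = 0.1
(apo K_d = 1.2 × 10⁻³/P μM). A second factor Q (default 1) splits that
cooperativity between on- and off-rates: k_on(apo) = k_on/Q, so Q = 1 puts
it entirely in the off-rate.

Assumptions that close the remaining degrees of freedom:

- **Lobe independence.** A site's Ca²⁺ constants do not depend on the other
  lobe's occupancy (the measured constants are per lobe and step only).
- **Shared loaded affinity.** All eight Ca²⁺-loaded CaM states bind CAMTA
  with the same K_d and rates.
- **Thermodynamic consistency.** Around every closed reaction cycle the
  product of equilibrium constants equals one (Wegscheider condition).

Under these, the bound-layer Ca²⁺ steps copy their free-layer counterparts
except the two edges leaving the apo·CAMTA state, whose K_d the cycle
condition forces down by exactly P. The rate split on those two edges is
not fixed by thermodynamics; the package keeps k_on equal to the free-layer
value and scales k_off, consistent with the Q = 1 convention of putting
cooperativity in off-rates. `wegscheider_check` verifies all 20 elementary
square cycles (12 Ca-step × CAMTA-binding, 8 N-lobe × C-lobe) to a relative
tolerance of 10⁻⁹ and detects injected violations.

The only concentrations are the conserved totals. Total CAMTA defaults to
its reference value 10 μM. Total CaM has no measured value; it defaults to
10 μM and carries a calibration operation (below).

## Equilibria: two independent routes

`steady_state` relaxes the stiff ODE system (BDF, analytic Jacobian) from
the apo/free state and polishes with a Newton root find on the reduced
system (apo-CaM and free CAMTA eliminated through the conservation laws, so
totals are preserved exactly); convergence requires max |d/dt| < 10⁻¹⁰
μM s⁻¹. `equilibrium_oracle` never integrates: every species is the product
of ca/K_d factors along any lattice path from apo (path-independent by the
Wegscheider condition) times the free apo-CaM and CAMTA concentrations,
which solve the two conservation equations by bracketed root finding. The
two routes agree to better than 10⁻⁶ relative across random parameter
draws; this is the module's central cross-check, kept as a dual-route test.

## Trajectory simulation

`simulate` integrates the clamped-Ca network with a stiff solver (BDF
default, analytic Jacobian, rtol = atol = 10⁻⁵; the absolute tolerance is
scaled six decades below the smaller total so rare species like `M22X` at
rest, ~10⁻⁵ μM, retain relative accuracy). The integration restarts at
every trace discontinuity — square waves are sampled with double points at
switch times — so the solver never steps across a jump. Between samples the
trace is linearly interpolated; beyond its ends, clamped. CaM and CAMTA
totals are conserved along trajectories to ~10⁻¹⁴ relative (checked to
10⁻⁶ in tests).

The initial state is always the equilibrium at the control (resting) Ca²⁺,
0.10 μM by default — the minimum of the reference oscillatory signature —
so every run starts settled and fold changes are well defined.

## Gene stage and delay

With m(t) = [M22X](t − τ) (τ = 600 s default), activation-mode mRNA obeys
d[mRNA]/dt = k₁ + k₂(m/k₄)ⁿ/(1+(m/k₄)ⁿ) − k₃[mRNA]; repression replaces
the Hill term with k₂/(1+(m/k₄)ⁿ). Defaults: k₁ = 5 × 10⁻⁶ μM s⁻¹,
k₂ = 5 × 10⁻² μM s⁻¹, k₃ = 3.75 × 10⁻⁴ s⁻¹, k₄ = 1.1 × 10⁻² μM, n = 2.
Because expression does not feed back on binding, the delay is implemented
by time-shifting the input (with the control level before signature start),
not by a delay-differential solver.

The mRNA balance is linear in mRNA, so it is solved exactly by an
exponential (integrating-factor) step per sample interval, treating the
production rate as piecewise linear between samples. This removes any
step-size-control error at square-wave switch times. One numerical caveat
found during development and handled in `decode`: the active-complex
trajectory has derivative kinks at switch times, so the binding-trajectory
output grid merges the trace's own sample times into the regular 0.1 s
grid; with that, the 1-h fold is stable to <10⁻³ against a reference run at
rtol = 10⁻¹¹.

## Analyses

- **Amplification** (`amplification_analysis`, `steady_state_amplification`):
  fold changes of Ca²⁺ and `M22X` against the control steady state. In the
  unsaturated regime the four-site ladder gives [M22X] ∝ Ca⁴, so a Ca fold f
  amplifies toward f⁴; at the reference conditions (control 0.10 μM, totals
  10 μM) 2-/4-/10-fold Ca elevations yield ≈14-, ≈170- and ≈3200-fold
  complex increases — the published circa 10/200/5000 within their stated
  "circa" precision. These folds are nearly independent of total CaM
  (within ~1% for 1–100 μM).
- **Decoding** (`decode`): settle → binding trajectory → delayed gene stage
  → mRNA fold at a readout time, 1 h after signature onset by default. A
  gene counts as induced at ≥ 1.5-fold, the experimental threshold.
- **History** (`history_trace`): the actual fold against the "potential"
  fold — the steady-state expression fold if the complex were held at each
  concentration indefinitely. Actual expression tracks but never exceeds
  the running maximum of the attainable potential, and end-of-cycle folds
  accumulate monotonically (the memory effect); after the signature the
  fold relaxes to 1 at rate k₃.
- **Scans** (`period_scan`, `duration_scan`): fold at readout versus period
  at fixed average/max/min/duration, and versus spike count at fixed
  period. Both run serially and deterministically.
- **Calibration** (`calibrate_cam_total`): total CaM is fixed by requiring
  a reference square wave (period 40 s, 400 s, average 0.16 μM, max 0.52,
  min 0.10) to produce a 6.0-fold change at 1 h; the root is bracketed by
  Brent's method after verifying monotonicity at the bounds, to a relative
  tolerance of 10⁻³. Self-recovery of a known total from its own readout is
  within 1%. The calibrated value under the defaults is ≈10.8 μM, close to
  the 10 μM CAMTA reference.

With that calibration the period scan gives 4.75-fold at T = 8 s, 6.0-fold
at T = 40 s (anchored) and 6.09-fold at T = 200 s: fewer, longer spikes
decode to larger expression changes, because the convex low-occupancy Hill
response rewards bursts of high complex concentration over the same average
delivered continuously, and less of the signature's effect has decayed by
readout. The published long-period value (6.6-fold at T = 200 s) is ~8%
above this reconstruction's; the spread between the 40 s and 200 s periods
is genuinely smaller here, and no admissible total-CaM value changes it
(the folds saturate in total CaM). The discrepancy is reported as is.

## Synthetic signatures

`make_piecewise` builds square waves from (average, max, min, period,
duration) via t_max = T(A − Ca_min)/(Ca_max − Ca_min); each cycle starts
with the high phase (phase is not otherwise constrained), discontinuities
are emitted as double points, and the default sampling step is 0.1 s.
`make_synthetic` provides smooth stand-ins for the three experimental
signature classes — raised-cosine spike trains (oscillatory), a linear rise
with exponential decay (transient), a smoothstep rise to a plateau
(prolonged) — with optional seeded Gaussian measurement noise. These
generators emulate the classes' shapes and summary statistics; they are not
fits to any measured trace, so quantitative results that depend on the
exact experimental waveforms (absolute fold values for the measured
signatures) are outside what passing tests demonstrate. What they do
establish: thermodynamic consistency, equilibrium correctness against an
independent oracle, conservation, super-linear amplification, delay and
accumulation behaviour, and the square-wave period/duration dependence.

## Numerical choices and degenerate inputs

- Steady state: relaxation spans grow ×10 from 10⁴ s until converged;
  Newton polish preserves totals; non-convergence raises with the residual.
- ca = 0 is a valid input (only apo species survive; the apo partition
  solves the single-site quadratic).
- Square-wave durations that are not whole multiples of the period warn and
  truncate to whole cycles.
- Trace files: two-column text (time_s, ca_um), 17-significant-digit
  output for bit-faithful round trips; malformed rows, backwards time and
  negative concentrations are rejected with row numbers.
- mRNA is clipped at zero after the (already positive) exact update;
  integration tolerances are stated per stage above.

## Known limitations

- The exact published system of ODEs is not independently available; the
  network is reconstructed from the stated reaction lattice, constants and
  thermodynamic constraints. The rate split on the two detailed-balance-
  corrected edges is a convention (k_off carries the correction).
- Gene expression is the simplest one-TF Hill mechanism; no promoter
  stochasticity, no translation, no combinatorial regulation.
- The delay is a single fixed lag, shared across genes and signatures.
- Experimental signatures are emulated, not digitized, so only qualitative
  claims are made for them.
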