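# Methods

## Circuit model and assumptions

The cell is represented as a lumped two-compartment RC network: the clamp
drives the surface membrane voltage `U_s` through the access resistance
`R_a`; the tubular membrane voltage `U_t` couples to `U_s` through the
lumen resistance `R_t`. Each membrane branch is a capacitance in parallel
with an ohmic resistance and a reversal-voltage source. The state equations
are linear:

```
dU_t/dt = U_s/τ_t − (k_t/τ_t)·U_t + k_Ut/τ_t
dU_s/dt = −(k_st/τ_s)·U_s + (k_at/τ_s)·U_t + (k_Us + U)/τ_s
```

with `τ_t = R_t·C_t`, `τ_s = R_a·C_s`, `k_t = 1 + R_t/R_mt`,
`k_st = 1 + R_a/R_ms + R_a/R_t`, `k_at = R_a/R_t`,
`k_Ut = U_mt·R_t/R_mt`, `k_Us = U_ms·R_a/R_ms`, and the measured current
`J = (U − U_s)/R_a`.

Assumptions inherited from the model: membrane conductances are constant
(linearization around the holding voltage, valid for small steps); the
tubular network is lumped into a single compartment (justified by tubular
length constants an order of magnitude larger than the cell radius); pipette
artefacts beyond a series access resistance are not represented.

The steady-state constants used throughout are re-derived from the state
equations (surface: `(k_t·k_Us + k_at·k_Ut + k_t·U)/(k_st·k_t − k_at)`;
tubular: `(k_Us + k_st·k_Ut + U)/(k_st·k_t − k_at)`) and are validated
against long-time ODE integration in the tests.

All internal arithmetic uses mV, MΩ, pF, nA and µs — a self-consistent
system (mV/MΩ = nA, MΩ·pF = µs) that keeps the characteristic polynomial
well scaled; trace time axes are in ms at the API boundary.

## Simulator

`simulate_step` integrates the state equations with LSODA
(rtol 1e-10, atol 1e-12) — the two time constants can differ by more than
10×, so a stiff-capable method is the default. The command edge is shaped by
an auxiliary first-order lag `dU/dt = (U_target − U)/τ_p`, solved jointly;
`τ_p = 0.05 ms` is the default edge, `τ_p = 0` an ideal step.

`simulate_train` exploits linearity: over each segment with a constant
command target the full (affine) system is propagated exactly through the
matrix exponential of the augmented system matrix, with trajectories
evaluated through its eigendecomposition. This is exact for the model and
fast enough to run 300-pulse trains routinely; it is cross-checked against
the stiff integrator in the tests. State is carried across pulses, so the
sweep sequence converges to the periodic steady state exactly as a real
train does. Recording noise is additive iid Gaussian per sample and sweep
(default σ = 0.01 nA — a placeholder, since the recordings' noise spectrum
is not characterized; pink/line noise is out of scope), reproducible from a
single seed; the averaged trace is the sample-wise mean of the last
`n_average` sweeps (default 50 of 300 at 25 Hz, 20 ms steps from −80 mV).
The default train amplitude is 10 mV (the experimental protocol used 10 or
5 mV; the larger step doubles the signal-to-noise ratio); the
verification-circuit runs use the 5 mV step (−80 → −75 mV) prescribed for
them.

## Bi-exponential decomposition

The descending transient is fitted with
`J_1·e^(−t/τ_1) + J_2·e^(−t/τ_2) + J_∞,2`. Three details matter:

1. **Edge handling.** A first-order command edge adds an exact third decay
   mode at τ_p and scales each circuit mode's onset-referenced amplitude by
   `1/(1 − τ_p/τ_i)` (residue calculus on the lagged step input — exact for
   a linear system). The default strategy (`edge_mode="model"`, used when
   τ_p is known) includes the τ_p mode as an extra component with fixed time
   constant, so the fitted model spans the exact noiseless response and the
   window can start at the current peak, keeping all fast-component
   information. The alternative (`edge_mode="exclude"`, for traces with
   unknown edges) starts the window at onset + 12·τ_p, where the edge mode
   has decayed to e⁻¹² of its amplitude; shorter delays (4–10 τ_p) measurably
   bias C_t (up to several percent at 10·τ_p for fast circuits, tens of
   percent at 4·τ_p).
2. **Amplitude referencing.** Fitted amplitudes are back-extrapolated from
   the window start to the step onset and corrected by `(1 − τ_p/τ_i)`, so
   the reported J_1, J_2 equal the ideal-step amplitudes and the extraction
   formulas apply literally. The raw windowed amplitudes stay in the
   diagnostics.
3. **Initialization.** A deterministic variable-projection grid: for each
   candidate (τ_1, τ_2) pair on a geometric grid the amplitudes and offset
   are solved linearly; the best residual seeds a bounded
   Levenberg–Marquardt refinement (lmfit; τ bounds [dt, 10·window]). This is
   seed-free and invariant under relabeling of the two components, which are
   afterwards ordered τ_1 ≥ τ_2. A ratio τ_1/τ_2 < 1.05 sets an
   "indistinguishable" flag (the mono-exponential, physiological-solution
   regime).

The pre-step steady current J_∞,1 is the mean of a baseline window
(default the 5 ms before onset) measured before the train, with its
standard error retained for error propagation.

The mono-exponential path (for physiological-solution records) reports the
whole-cell capacitance from the transferred charge `Q = J_amp·τ` as
`C_total = τ·jump²/(J_amp·ΔU)` with `jump = J_amp + (J_∞,2 − J_∞,1)` — the
squared factor corrects the access/membrane voltage divider and is exact
for a single-compartment cell.

## Element extraction

`R_a`, `C_s`, `R_1 = R_ms‖R_t` and `R_2 = R_ms‖(R_t + R_mt)` follow from
closed-form expressions. The closure `G_mt/G_ms = γ·C_t/C_s` leaves one
unknown pair (k, R_ms) constrained by two relations: the physical root of
the quadratic `R_ms² − R_ms(R_1 + R_2 + (R_2 − R_1)γk) + R_1R_2 = 0` and
the rational relation `R_ms = (γk − 1)R_1R_12/(kR_1 − R_12)` with
`R_12 = (R_a/τ_s)(τ_1J_2 + τ_2J_1)/(J_1 + J_2)`. Equating them and clearing
denominators gives a cubic in k whose constant term vanishes identically;
deflating the structural k = 0 root leaves a quadratic solved in closed
form. Roots are filtered by physicality: positive k, R_ms on the "+" branch
of the quadratic (the "−" branch is computed and rejected with a logged
reason), R_ms > R_1, and a quadratic residual below 1e-8·R_ms². A
bracketing scan was rejected because the genuine root can sit arbitrarily
close to the pole of the rational relation (it does for expected γ ≳ 1.15
in the γ-robustness configuration) where grid sign-change detection fails;
the closed form has no such blind spot. An independent 2-D grid-search
oracle verifies the solver in the tests.

Derived elements: `C_t = k·C_s`, `R_t = R_1·R_ms/(R_ms − R_1)`,
`R_mt = R_ms/(γk)`, `C_m = C_s + C_t`, `f_t = k/(1 + k)`. The simplified
estimator `C_t ≈ ((τ_1J_2 + τ_2J_1)/(J_1 + J_2))·k_c/R_1` (k_c = 0.97
ventricular, 0.91 atrial) is available alongside for comparison with the
earlier two-capacitance-only workflow.

The reversal-voltage estimate assumes `U_ms = U_mt`:
`U_rev ≈ U_1 − J_∞,1·R_a/(1 − a)`. The second printed form
(`U_2 − J_∞,2·R_a/(1 − a)`) is algebraically identical given consistent
inputs, so their difference is retained only as a numerical consistency
check; when the true reversal voltages differ the estimate falls between
them, and C_s, C_t, f_t are unaffected by either reversal voltage.

Defaults for the expected γ: 1.2 for experimental ventricular data (the
value that best matched independently obtained capacitance estimates), 0.7
(mid range of 0.4–1.25) in synthetic verification work.

## Uncertainties

`CapacitiveTransientResults.bse` propagates the least-squares covariance of
(J_1, J_2, τ_1, τ_2, J_∞,2) — transformed to the reported, edge-corrected
amplitudes — plus the independent baseline variance through the extraction
map with a central-difference jacobian (delta method). These are
fit-precision errors; they do not include the systematic effect of a
mis-specified γ, which the γ-sensitivity sweep quantifies separately.

## What the synthetic data does and does not emulate

The generator reproduces the stimulation protocol (pulse trains with shaped
edges, steady-state sweeps, last-50 averaging) and additive white recording
noise. It does not emulate: amplifier filtering or series-resistance
compensation, 1/f and line noise, slow drift of seal or access resistance,
incomplete or time-varying sucrose wash-in, or voltage-dependent membrane
conductances. Passing tests therefore demonstrate correctness of the
analysis chain under the model's own assumptions — they do not certify
performance on recordings whose artefacts fall outside this list; the
acceptance criteria (R_2, R_1/R_2, R_a shift, J_1/J_2, τ_1/τ_2) are the
instrument for rejecting such recordings.

Noise performance at the defaults (σ = 0.01 nA, 50-sweep averaging, 10 mV
step): the recovered C_s and C_t are accurate to better than 2% RMS over
repeated noise realizations; the decomposition operates near the efficiency
limit of least squares for this model, so individual realizations can reach
~3σ of that figure, and a 5 mV step doubles the spread.

## Numerical choices

- Characteristic rates from the stable quadratic formula (large root
  explicitly, small root via the product) — no cancellation for widely
  separated time constants.
- Equal time constants (tau ratio below 1 + 1e-9 in the closed form,
  1.05 in fits) are reported as degenerate/indistinguishable rather than
  silently inverted.
- Default sample interval 10 µs (resolves τ_2 of a few hundred µs in the
  sucrose regime); a dt coarser than τ_2/10 records a warning in the trace
  metadata.
- Trace files store floats at %.17g, making write/read round trips exact.
- Problem sizes in the verification suite: 20 ms pulses at 10 µs sampling
  (2 501 samples), 100-circuit randomized round trips, 18-point γ grids,
  5-point element sweeps — each chosen to keep the full suite in the
  single-digit minutes while exercising every claimed bound.

## Known limitations

- γ is assumed, not estimated; the extraction quantifies sensitivity to it
  but cannot identify it from a single transient.
- The ~18% reduction of total capacitance in sucrose relative to Tyrode
  solution is an observed phenomenon, surfaced only as the C_m/C_Tyr
  comparison in experimental workflows; no correction is applied.
- Distributed (cable) tubular models, nonlinear conductances and ionic
  current dissection are out of scope.
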