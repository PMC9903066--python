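# Methods

This note documents the models, numerical choices and known limitations of
`teerkit`. It is written for users who want to know exactly what the package
computes and what the synthetic-data generator does and does not emulate.

## Measurement model

### Chip equivalent circuit

A perfused microfluidic barrier chip is modeled as a series resistance in
series with the paracellular barrier:

```
Z(f) = R_s + R_b / (1 + R_b · q · (j·2πf)^α)
```

- `R_s` (Ω): medium + channel path resistance. Typical value in a 3-lane
  chip with electrodes in the perfusion inlets/outlets: ~25 kΩ.
- `R_b` (Ω): paracellular barrier resistance — the quantity of interest.
- `q` (S·s^α), `α` (–): constant-phase element (CPE) describing the
  distributed capacitance of the cell layer; `α = 1` is an ideal capacitor.
  The CPE branch impedance is `1/(q·(jω)^α)` with the principal branch of
  the complex power.

This is a *modeling choice*, not a measured fact about any particular
instrument: it is the minimal topology producing a low-frequency plateau at
`R_s + R_b`, a high-frequency plateau at `R_s`, and a dispersive transition,
which is what makes "barrier resistance" a well-defined fitted parameter.
Electrode–electrolyte interface impedance, Warburg/diffusion elements and
multi-dispersion models are deliberately out of scope.

TEER is the fitted barrier resistance times the approximate cell–matrix
interface area, default **0.0057 cm²** (`teer = R_b × area`, Ω·cm²). The
area is a config constant, not hard-coded, because it approximates a real
contact geometry.

### Parasitic network and three-load compensation

The electrode path adds a series lead resistance `R_lead` and a parallel
stray capacitance `C_par`. Any linear one-port distortion — including this
one — acts per frequency as a bilinear (fractional linear) map

```
Z_m = (a·Z + b) / (c·Z + 1),
```

with the denominator constant fixed to 1 to remove the gauge freedom.
Three boards with known resistors in place of the chip electrodes (defaults
24, 30, 36 kΩ) identify `(a, b, c)` exactly at each frequency; with more
loads the system is solved in the complex least-squares sense. Compensation
inverts the map: `Z = (b − Z_m)/(Z_m·c − a)`.

Numerical notes:

- The per-frequency 3×3 system has columns spanning ~9 decades
  (`R`, `1`, `−M·R`), so it is column-equilibrated before the conditioning
  check and solve. The exactly-determined case is solved by Cramer's rule in
  extended precision: when two loads are close, identification conditioning
  degrades as roughly the square of the load-range/gap ratio, and plain
  double precision can lose several coefficient digits. With loads separated
  by ≥ ~2% of their range, round-trip recovery is accurate to ~1e−11
  relative; truly coincident loads are rejected as singular. Real board
  sets space their resistances far apart (the defaults are 25% apart)
  precisely because calibration is an interpolation problem.
- Points where the inverse-map denominator falls below a configurable floor
  are flagged invalid rather than producing wild values; downstream fitting
  ignores flagged points.
- A warning is emitted when a compensated spectrum's median magnitude lies
  more than 10× outside the calibration load range: the compensation is then
  extrapolating.
- Coefficients are not smoothed across frequency.
- Error models can be estimated per chip path or shared per plate; the
  pipeline default estimates one model from one board set.

### Why compensation matters (and its noise cost)

Inverting the error map also inverts its gain: if the network attenuates the
high-frequency signal by a factor g, compensation amplifies measured noise
at those frequencies by ~1/g². With a 100 pF stray at a 25 kΩ level the
attenuation at 1 MHz is ~16×, i.e. a ~250× noise amplification — the
compensated spectrum is then noise-dominated at high frequency and barrier
recovery becomes noise-limited well short of the precision the rest of the
chain supports. The generator's default stray (10 pF, a PCB-trace-level
value) keeps the simulated instrument in the usable regime that a working
measurement system necessarily occupies, while still bending the spectrum
visibly near 1 MHz.

## Fitting

The chip model is fitted to a compensated spectrum by complex nonlinear
least squares:

- Cost: `Σ_f |Z_model(f) − Z_data(f)|² / w(f)` with modulus weighting
  `w = |Z_data|²` (default), so both plateaus contribute comparably across
  the three-decade sweep; unit weighting is available.
- Optimizer: trust-region reflective least squares (scipy) on
  log-transformed parameters, which enforces positivity and makes the
  `q`/`α` scale trade-off better behaved. Bounds (log-space box):
  `R_s ∈ [1, 10⁷] Ω`, `R_b ∈ [10⁻³, 10⁷] Ω`, `q ∈ [10⁻¹³, 10⁻²]`,
  `α ∈ [0.3, 1]`. The `R_b` floor doubles as the "no barrier" resolution.
- Initial guess from the data: `R_s` ← real part at the highest valid
  frequency; `R_b` ← low-frequency real part minus `R_s` (floored); `α` ←
  0.9; `q` ← value placing the barrier corner at the frequency of the most
  negative imaginary part.
- Multistart (default 3): the data-driven guess plus perturbed copies drawn
  from a generator with a fixed internal seed, so fitting is deterministic
  for fixed inputs and options. Guards against the shallow `q`/`α` valley.
- Non-convergence is flagged (`converged=False`), never raised; the best
  result found is returned.
- Identifiability guard: if the fitted barrier corner frequency
  `(1/(R_b·q))^{1/α} / 2π` falls below the sweep minimum, the barrier
  plateau was never observed and the result carries the
  `barrier_underdetermined` flag.

### What recovery precision to expect

A Fisher-information (Cramér–Rao) analysis of the default acquisition
conditions — 121 log-spaced points, 1 kHz–1 MHz, 1% relative per-part noise,
`R_s ≈ 25 kΩ` — shows the standard error of `R_b` is roughly constant in
absolute terms (~50–100 Ω, depending on the CPE), because the barrier rides
on a 25 kΩ background measured with ~250 Ω per-point real-part noise. So
relative recovery error grows sharply for barriers below ~500 Ω; a 200 Ω
barrier cannot be recovered to better than ~25–40% at these settings no
matter the estimator. Parameter-recovery claims in the test suite are stated
against this envelope.

## Synthetic acquisition

The generator replaces the plate reader. What it emulates:

- **Plate**: 64 chips on an 8×8 logical grid, 8 electrodes per chip
  (4-terminal loops shorted pairwise in inlet/outlet), 512 electrodes total,
  6 microtiter wells per chip.
- **Sweep**: 121 points, log-equally spaced, 1 kHz–1 MHz inclusive.
- **Noise**: independent Gaussian perturbation of each measured point's real
  and imaginary parts, each with SD `sigma_rel` × that part's own magnitude.
  Default `sigma_rel = 0.5%` in the example config; 1% in the recovery
  studies.
- **Inter-chip variability**: seeded lognormal multiplicative factors
  (σ = 10%) on baseline `R_s`, `R_b`, `q`.
- **Baseline chip**: `R_s = 25 kΩ`, `R_b = 2 kΩ`, `q = 5.7×10⁻⁹ S·s^α`
  (≈1 µF/cm² of cell-layer capacitance over the 0.0057 cm² interface),
  `α = 0.95`. The CPE default was set from that physical scale together with
  the identifiability analysis above: it places the barrier corner inside
  the sweep for the barrier range of interest.
- **Schedule**: baseline reading at −6 min (the pre-exposure T₋₁), a
  reading at exposure (t = 0), every 4 min through 44 min, every 64 min
  through 43 h, one endpoint at 46 h (inside the 44–48 h endpoint window).
  All intervals are configurable; published timelapse protocols differ in
  how they count the fast-phase points, so the counts here follow the
  arithmetic of the stated intervals rather than any fixed total.
- **Treatment scenarios** (true barrier trajectories, all strictly
  positive):
  - `control`: constant baseline.
  - `ifng` (IFN-γ-like): `R_b(t) = R_b(0)·exp(−k·E(dose)·t)`, slow
    dose-dependent decline, `k = 0.012 /h` at saturation (~40% loss by
    44 h).
  - `tnfa` (TNFα-like): gamma-pulse dip
    `R_b(t) = R_b(0)·(1 − d·E(dose)·(t/τ)·e^{1−t/τ})`, `τ = 2 h`,
    `d = 0.5` at saturation: a sharp dip bottoming at 2 h that recovers to
    baseline well before 44 h.
  - `combo` (TNFα+IFN-γ-like): same onset speed
    (`1 − e^{−t/1 h}` ramp) and saturating depth, but the floor persists —
    no recovery.
  - `disruptor` (staurosporine-like): `R_b(t) = R_b(0)·e^{−t/1 h}`, rapid
    monotone collapse toward zero.
  - Dose dependence: Hill factor `E(dose) = dose²/(dose² + 1.5²)` (ng/ml):
    responses at 10 and 100 ng/ml differ by <2% of baseline (saturation)
    while 0.1 and 1 ng/ml remain clearly dose-ordered.
- **Seeding**: one top-level seed; per-chip and per-timepoint generators are
  spawned deterministically (`numpy` SeedSequence), so datasets are
  reproducible bit for bit.

What it does **not** emulate — and what passing tests therefore do not show
about real data: electrode drift and temperature effects, electrode–
electrolyte interface dispersion, biological replicate structure beyond a
lognormal baseline spread, frequency-correlated instrument noise, chip
failures/bubbles, and any coupling between chips. The excitation amplitude
(100 mV in the emulated class of instruments) is metadata only: impedance of
a linear circuit is amplitude-invariant.

## Timelapse analytics

- Relative trajectories are per-chip: each chip is divided by its own T₋₁
  baseline fit. This removes chip-to-chip baseline variation and matches
  the pre-exposure baseline measurement taken per plate; normalizing to the
  first post-exposure point instead would hide effects faster than the
  first interval. Chips with non-positive baseline are excluded and logged.
- Group summaries: mean, SD, n of relative TEER per condition and
  timepoint; fits flagged non-converged are excluded from that timepoint's
  n.
- Transient metrics: nadir (minimum of the relative trajectory), its time,
  and endpoint recovery = (mean of the final 4 h window) / nadir. Recovery
  ratios well above 1 indicate a transient (TNFα-like) response; ~1
  indicates sustained loss (combination-like) — or a trajectory whose
  nadir is at the end.
- Dose-ordering check: group means at the summary timepoint closest to the
  requested time, tested for monotone non-increase in dose with a
  configurable tolerance (needed at saturating doses).
- No significance testing: outputs are tidy tables for external statistics
  packages.

## Problem sizes used in the automated checks

The acceptance script and test suite run at desk scale, chosen to finish in
minutes on one CPU while exercising every code path at the plate's full
width: compensation exactness over 200 random networks on the full 121-point
grid; parameter recovery over one 64-chip plate (barriers cycling through
200/500/1000/2000/5000 Ω) at 1% noise; phenotype analysis on a 13-chip
noiseless panel (control + 4 doses × 3 cytokine scenarios) over the full
default schedule; determinism on a 4-chip, short-schedule pipeline run twice.

## Known limitations

- The fitted `α`/`q` pair trades off against `R_s` on short sweeps; the
  multistart mitigates but does not eliminate this, and `q` is the least
  well-determined parameter (~50% relative SE at 1% noise).
- Compensation assumes the parasitic network is identical between the board
  measurement and the chip measurement, and stable over the timelapse;
  temperature drift is out of scope.
- Barriers whose corner frequency lies below 1 kHz are reported but flagged
  underdetermined; barriers below a few hundred Ω are noise-limited (see
  the recovery envelope above).
- The scenario library is phenomenological: it reproduces the qualitative
  shapes and dose saturation of cytokine responses, not any fitted kinetic
  constants.
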