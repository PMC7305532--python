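# Methods

## Mechanical model

The archwire segment between the two anchorage teeth is treated as a simply
supported Euler–Bernoulli beam: span `l` (anchorage distance), point load `P`
at `x = a` (offset distance from the distal support, `b = l − a` to the
mesial one), small deflections, no axial force, and — following the tight
ligation assumption — no sliding friction between wire and brackets. The
orthodontic force is the reaction to the load producing the imposed root-ward
displacement `d` of the target tooth, so it is linear in `d`, `E` and `I_z`.

Integrating `v'' = M(x)/(E I_z)` with `M(x) = (Pb/l)x − P⟨x−a⟩` and
`v(0) = v(l) = 0` gives the standard two-branch deflection profile

```
v(x) = −(P b x)/(6 E I l) · (l² − x² − b²)                    0 ≤ x ≤ a
v(x) = −(P b)/(6 E I l) · [ (l/b)(x−a)³ + (l²−b²)x − x³ ]     a ≤ x ≤ l
```

whose load-point value implies the stiffness `F = 3 E I l d/(a² b²)` (the
`rederived` variant). The `printed` variant `F = 6 E I d/(a(l²−a²−b²))`
(note `l²−a²−b² = 2ab`) drops a factor `b/l` relative to this profile —
for `a = b` it is exactly half the classic `48 E I/l³` centre-load
stiffness, while `rederived` equals it. Because the historical calibration
was built on the `printed` form, that form is the default baseline;
calibrated coefficients record their variant, and validation refuses to mix
variants. Both variants are verified in the test suite against brute-force
double numerical integration of the curvature (a scipy
`cumulative_trapezoid` oracle that only uses the bending-moment statics).

Cross-sections: `I_z = π d⁴/64` for round wire, `I_z = w h³/12` for
rectangular wire with `h` the dimension lying in the deflection
(occlusal–gingival) plane. In the archwire naming code the **first**
dimension pair is taken as that deflection-direction dimension. This is the
standard-mechanics reading, and it is the one the measurements support: the
measured force ratio of `S20102007` to the reference wire (1.93 at equal
displacement, after accounting for its `a = 7 mm`) matches cubing 0.020″
(predicted 1.92), whereas cubing 0.010″ is off by a factor of four.

Internal units are SI (m, Pa, N) throughout; public interfaces take
millimetres for displacements and distances (clinical convention) and return
newtons.

## Material moduli

The bench study the packaged dataset comes from names its two wire types but
not their moduli, so the package carries two built-in libraries:

* **textbook** (default): stainless steel `E = 1.79×10¹¹ Pa`, Australian
  wire `E = 1.57×10¹¹ Pa` (the stainless value scaled by the measured
  stiffness ratio of the two wires, ≈0.88), both `μ = 0.3`;
* **effective** (`EFFECTIVE_MATERIALS`, used by
  `CorrectionFactorModel.reference_study()`): `E_S = 7.92×10¹⁰ Pa`,
  `E_A = 6.97×10¹⁰ Pa`. These are identified from the published correction
  functions themselves: the refit anchorage slope equals the published
  −2.2245 %/mm only at `E_S ≈ 7.92×10¹⁰` (giving −2.2245·l + 63.27 against
  the published −2.2245·l + 62.561), and the published material slope then
  pins `E_A` (ratio 0.880). They are best read as effective moduli of that
  measurement setup rather than material properties.

The distinction matters only for comparing refit coefficients with the
published ones: the per-archwire validation errors are invariant under a
uniform rescaling of the baseline (the correction-rate fits are affine in
that scale, and the error ratios cancel it), which the test suite exploits.
Poisson's ratio and the cross-sectional area are carried on the domain types
for completeness but no implemented equation consumes them.

## Calibration

Correction rates `100 (F_exp − F_theo)/F_theo` are computed per (archwire,
displacement) cell and aggregated per archwire by the mean over the ten
displacements (median available; rates are nearly displacement-free because
both model and data are close to linear in `d`). Cells with a vanishing
force are excluded with a logged warning. The parallel deviation rate
`100 (F_exp − F_theo)/F_exp` satisfies `(1 + corr/100)(1 − dev/100) = 1`
and is reported alongside.

Each correction function is an unweighted OLS fit of the aggregated rates of
one comparison group (every group contains the reference wire `S16162010`):
anchorage — linear in `l` (4 wires); offset — quadratic in `a` (4 wires);
section — linear in `ln(I_z·10¹⁵)` (3 wires); material — linear in
`E·10⁻¹⁰` (2 wires, exactly determined, so its coefficient standard errors
are undefined). Groups are classified automatically from the parsed codes;
a group with fewer wires than fit parameters raises an error naming it.
Diagnostics (residuals, R², coefficient standard errors where the degrees of
freedom allow) are stored with the coefficients, which serialize to JSON.

The composed factor multiplies the baseline: `F = K_F·F_theo`. With the
correction rate defined against the theoretical value, `K = 1 + rate/100`
satisfies `F_theo·K = F_exp` cell-wise, making the multiplicative convention
the internally consistent one; a `divide` switch exists for fidelity
experiments. No cross-terms are fitted — multiplying unnormalized
single-parameter factors would over-correct, hence the base normalization.

### Base normalization

`K_F = K_Fl · K_Fa/K_Fa0 · K_FS/K_FS0 · K_FM/K_FM0` needs the three base
values at the reference wire, and two conventions are defensible:

* `base_mode="fitted"` (default): each fitted function evaluated at the
  reference parameters. The three ratios are then exactly 1 at the
  reference, giving the clean identity `K_F(ref) = K_Fl(l_ref)`.
* `base_mode="measured"`: the reference wire's empirical mean correction
  factor for all three. This shields the composition from each group fit's
  residual *at the reference point*. The distinction is material for the
  section group, whose three points are distinctly non-collinear in
  `(ln I, rate)` space: under `fitted` the reference residual propagates
  into every section-group prediction through `K_FS0`, and the maximum
  per-archwire mean error on the packaged data is 10.7 %; under `measured`
  it is 8.5 % (range 4.3–8.5 %), inside the 8.75 % bound the reference
  study reports. `reference_study()` therefore calibrates with
  `measured`, and every report records which convention produced it.

### The offset-comparison wire

`S20102007` nominally has a 0.020″ × 0.010″ section, yet it functions as the
`a = 7 mm` member of the offset group. Refitting with its theoretical force
computed from the reference 0.016″ × 0.016″ section reproduces the published
offset function almost exactly (8.537 a² − 153.76 a + 703.74 against the
published 8.555 a² − 153.941 a + 703.031); computing it from the literal
section does not (1.97 a² − 34.3 a + 164). The original calibration
evidently treated the wire as a pure offset variant, so the reproduction
protocol parses it via the substitution `S20102007 → S16162007` (a parser
option; literal parsing remains the default elsewhere, with a warning that
the section effect contaminates the offset fit).

## Identifiability

`K_F` is invariant under rescaling any of the three normalized functions
(the base ratio cancels), so raw polynomial coefficients are identified only
up to an affine family. `CorrectionCoefficients.normalized()` fixes the
gauge by rescaling `K_Fa`, `K_FS`, `K_FM` to equal `K_Fl(l_ref)` at the
reference parameters; coefficient comparisons (and the simulation ground
truth) live in this gauge. Recovery of the calibration from synthetic data
is judged on the *function values* over the calibrated ranges — the
quantities the data actually determine. The raw material-slope coefficient
in particular is a near-null effect (the two wires' corrections differ by
≈0.1 percentage points) and is individually unrecoverable at realistic
noise, which the recovery experiment's per-coefficient RMSE makes visible.

## Synthetic data

The generator emulates the bench design: each cell is
`K_F,true(spec) · F_theo(spec, d) · (1 + ε)` with `ε ~ N(0, σ²)` truncated
by redraw to keep forces positive, independent across cells and replicates;
replicates are averaged as in the bench protocol. Defaults: the ten-code,
ten-displacement design (with the offset wire as `S16162007`, so the table
lies exactly in the fitted model class), `σ = 0.02` (inside the quoted <5 %
manual measurement error), 3 replicates, truth = the published coefficients
in the identifiability gauge at the effective moduli. Fixed seeds make
output bit-reproducible; ensemble seeds derive from a `SeedSequence`.

What passing recovery tests show: the estimator is consistent for data that
follow the multiplicative-correction beam model with independent
multiplicative noise. What they do not show: robustness to friction
hysteresis, load-history effects, sensor cross-talk, non-multiplicative
error, or cross-parameter interactions — none of which are simulated, and
the last of which the single-parameter composition cannot represent even in
principle.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on Vandermonde designs (systems are 2–4
  points; conditioning is irrelevant at these sizes).
* Closed-form beam expressions evaluated branch-wise; the profile grid
  always contains the load point, where the branches agree to machine
  precision.
* Degenerate geometry (`l² − a² − b² ≤ 0`) cannot occur for `0 < a < l` but
  is guarded; zero displacement returns exactly zero force.
* Extrapolating a correction function outside its calibrated range warns
  (`ExtrapolationWarning`) rather than fails.
* CSV forces are written at two decimals (the measurement resolution);
  displacement values keep their natural decimals so files round-trip
  bit-identically.

## Validation protocol and limitations

Validation on the calibration table is the reference study's own protocol —
it has no holdout — and every report carries an explicit in-sample label;
the error range is a goodness-of-fit statement, not out-of-sample accuracy.
Reports include both the per-archwire mean error range (the headline
figures) and the per-point extremes, since a bare "error range" can mean
either. No uncertainty is attached to the error rates. Scope is the
unidirectional vertical force of the second sequential loop only: no
buccolingual forces, torque, friction, or multi-loop interaction.

Problem sizes throughout (10×10 table, ≤50-seed ensembles, 13-point
function-recovery grids, ~4000-point integration oracle) were chosen as the
smallest at which the checks are statistically meaningful; all computations
run in seconds.
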