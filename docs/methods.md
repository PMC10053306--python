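# Methods

## Model families and their assumptions

All four models are empirical descriptions of solid–liquid extraction
curves, monotone nondecreasing in time for valid parameters:

- **First-order**: uptake rate proportional to the remaining extractable
  pool, `dC/dt = k₁(C_eq − C)`, giving `C_t = C_eq(1 − e^(−k₁t))`. Two
  saturating parameters: the asymptote `C_eq` (response units) and the
  rate `k₁` (min⁻¹).
- **Peleg hyperbolic**: the closed-form solution of the second-order law
  `dC/dt = k₂(C_eq − C)²`, re-parameterized as `C_t = C_eq·t/(k₂′ + t)`
  with `k₂′ = 1/(C_eq·k₂)` the time at half saturation. The package
  treats `k₂′` as the fitted parameter and exposes `k₂` through
  `second_order_rate`, since `k₂′` has time units and a direct data
  interpretation while `k₂` mixes time and concentration units.
- **Elovich**: `C_t = E·ln t + a`, the integrated form of a leaching rate
  that decays exponentially with yield. Undefined at `t ≤ 0`: evaluation
  there is an error, never an extrapolation, and consequently datasets
  must start at `t > 0` (the standard schedule starts at 1 min). `a` (the
  1-minute concentration) may take either sign; `E > 0`.
- **Power law**: `C_t = B·tⁿ` with `n` constrained strictly inside
  (0, 1), the diffusion-limited regime; with `n > 0` the value at `t = 0`
  is exactly 0, so no `0⁰` case arises.

Concentration units are opaque labels (`%`, `g GAE/100 g`, …); nothing is
converted. First-order and Peleg values never exceed `C_eq`; the
first-order residual at `t = 20/k₁` is below `10⁻⁸·C_eq`, which the tests
assert.

## Fitting

The objective is always the sum of squared errors on the original
response scale, `SSer(θ) = Σᵢ (Cᵢ − model(θ, tᵢ))²` — no linearizing
transformation of the response is ever applied. Minimization uses
`scipy.optimize.least_squares` with the bounded trust-region-reflective
method, a Levenberg–Marquardt-class algorithm that honors the parameter
boxes (positivity; `n ∈ (0.001, 0.999)` for the power law, with a
`bound_hit` flag when a solution lands on a box edge). Convergence
tolerances default to 10⁻¹⁰ (gradient, step, cost) with at most 500
function evaluations per start.

Initial guesses are data-driven: `C_eq⁰ = 1.02·max(C)` and `k₁⁰` from a
regression of `−ln(1 − C/C_eq⁰)` on `t` over pre-plateau points
(first-order); `C_eq⁰ = 1.05·max(C)` and `k₂′⁰` = earliest time the
response reaches half of `C_eq⁰` (Peleg); ordinary least squares on
`(ln t, C)` and `(ln t, ln C)` for Elovich and power law. Constant-valued
data is flagged degenerate and given bounds-safe defaults. A seeded
multistart (default 5 = the guess plus 4 log-uniform ±50% perturbations
of it) guards against local minima; the lowest-SSer run is kept, and the
descent property `SSer(fit) ≤ SSer(guess)` is asserted in tests.

The Elovich model is linear in `(E, a)`, so it is solved in closed form —
the exact global optimum. This is still "without linearization" in the
sense that matters: the response is fitted on its own scale. Weighted or
robust losses, and parameter confidence intervals, are out of scope.

Whether the conventional origin point `(t=0, C=0)` belongs in the fit is
left open by the data conventions of the field; this package excludes it,
as required jointly by the Elovich domain and the AARD statistic.

## Goodness of fit and comparison tables

`R²` uses the total sum of squares about the observed mean — the only
definition consistent with `R² ≤ 1` for all reported fits — and is
undefined for constant observations. `AARD` divides by the observed value
(hence the strict positivity requirement on data) and carries the 100×
percent factor. A comparison table holds one row per (power, model) with
the fitted parameters and the three statistics, sorted by canonical model
order then power, and appends per-model mean rows: unweighted arithmetic
means over exactly the powers present. Internal values keep full
precision; rendering rounds half-up to the printed precision (parameters
and R²: 3 decimals; SSer: 3; AARD: 2). One published mean is printed as
2.123 in tabular form and 2.12 in prose; both are roundings of the same
full-precision mean (2.1228), which the package keeps.

## Power profile and spline optimum

The profile collects `(P, k₁)` from converged first-order fits at ≥ 3
powers. Interpolation uses a **natural** cubic spline (zero second
derivative at both end knots): the boundary condition is not dictated by
the underlying claim ("cubic spline"), and natural boundaries are the
choice that does not invent curvature beyond the measured range. With the
five published TP knots it places the interior maximum at 664.76 W with
value 2.364 min⁻¹ — consistent with the published rough estimate of
2.36 min⁻¹ at 665 W, whose stated tolerance the acceptance test carries
(±25 W, ±0.05 min⁻¹).

The maximum is found analytically, not by numeric search: on each piece
the derivative is a quadratic, so the candidate set (piece endpoints plus
real derivative roots inside the piece) is exhaustive. Ties break toward
the lowest power. `at_knot` records whether the argmax sits on a knot
(e.g. for monotone profiles). Tests cross-check the spline coefficients
against an independent tridiagonal solve of the natural-spline
second-derivative system and the argmax against a 10⁵-point dense grid.
Evaluation outside the measured power range raises; extrapolating a
five-knot interpolant has no physical warrant.

## Synthetic data

The generator forward-simulates any model family on the study's sampling
schedule (1, 2, 3, 4, 5, 7.5, 10, 15, 20, 25, 30 min — dense early where
the curve moves, sparse on the plateau) at the five-power design
(90–800 W), with:

- additive, homoscedastic Gaussian noise (no error model is published for
  such assays; homoscedastic is the simplest defensible default), either
  absolute (response units) or relative to `C_eq` (spectrophotometric
  error typically scales with signal);
- optional degradation: the clean curve is multiplied by
  `exp(−r·(t − t_d))` for `t > t_d`, the simplest shape matching the
  post-15-min decline of yield and phenolics observed at high power. It
  deliberately creates misfit for all four families so model-robustness
  can be probed;
- point-wise redraw of non-positive values (up to 100 rounds, then an
  error — unreachable in practice for symmetric noise, kept as a guard);
- full seed control. Power-series seeds derive as `base_seed + rank of
  the power in ascending order`, so each power's noise realization is a
  stable function of (base seed, power) and independent of the order the
  powers are listed in.

Default study conditions are the published ones: the five powers with
their published TP first-order rate constants (0.403–2.284 min⁻¹),
`C_eq = 9.2 g GAE/100 g` (the approximate common asymptote; the published
per-power values are power-insensitive, 8.74–9.47), 2% relative noise in
the CLI simulator.

What the generator does **not** emulate: microwave physics (temperature
or solvent-property profiles), replicate structure or between-batch
variance, heteroscedastic assay error, and compound-specific degradation
chemistry. Passing recovery tests therefore show the estimation machinery
is correct and well-conditioned under the stated noise model, not that
real extracts obey first-order kinetics.

## Numerical and design notes

- Noiseless synthetic curves are recovered to ≤ 10⁻⁶ relative error with
  SSer below 10⁻¹⁶ (machine-precision identifiability on 11 points).
- At σ = 2% of `C_eq` on the standard schedule, the median relative
  recovery error over 200 replicates is ≈3.7% for `k₁` and ≈0.4% for
  `C_eq`. Rate constants above ≈2 min⁻¹ are intrinsically hard under this
  schedule — only the 1-minute sample constrains them, so their
  estimation SD (≈0.2 min⁻¹) is near the information bound, and the
  spline optimum inherits that spread. The optimum-stability test
  (optimum within ±60 W / ±0.15 min⁻¹ of the zero-noise optimum in ≥ 90%
  of replicates) therefore runs at absolute σ = 0.02 response units,
  where it holds with margin; no such bound can hold at 2%-of-`C_eq`
  noise with this design.
- Replicate counts in the statistical tests (200 for recovery, 100 for
  model selection and optimum stability, 10 datasets per family for the
  brute-force cross-check) are the package's chosen problem sizes: large
  enough for stable medians and proportions, small enough to keep the
  suite fast.
- Display rounding is half-up via `decimal` (locale-independent);
  `repr`-based CSV writing plus round-trip float parsing makes
  write→read→write byte-identical.

## Known limitations

- The published per-power parameter values cannot be re-fitted from
  scratch: the underlying kinetic observations were published only as
  plotted points, so they enter this package as bundled printed summaries
  (fixtures and generator settings), never as refit targets.
- No TF-specific modeling exists: total flavonoid datasets are accepted
  as inputs like any labeled response, but the published analysis itself
  excluded TF from modeling.
- Single-response, single-factor scope: no mechanistic (Fickian PDE)
  models, no temperature dependence, no multi-phase washing+diffusion
  forms, no smoothing splines or response-surface optimization.
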