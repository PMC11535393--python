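# Methods

## Pathway model

The design model is the minimal chain that captures a strain panel built for
in vivo enzymology:

```
dS/dt = v_in − Vmax·S/(K + S)          (− µ·S if dilute_intermediate)
dP/dt = Vmax·S/(K + S) − µ·P
```

with `v_in` the constant substrate-producing flux (µM/h), `Vmax` (µM/h) and
`K` (µM) the parameters of the converting enzyme, and `µ` (h⁻¹) the specific
growth rate that dilutes the product. Units are fixed to µM and hours
everywhere outside `quantify`.

Assumptions: the substrate-producing step is zero-order (saturated or
flux-controlled upstream enzyme); the conversion is irreversible
Michaelis–Menten; the product is chemically stable, neither secreted nor
degraded, so growth dilution is its only sink. By default the substrate pool
is **not** growth-diluted (`dilute_intermediate=False`), which gives the
closed form

```
S* = K·v_in/(Vmax − v_in),   flux* = v_in,   P* = v_in/µ     (v_in < Vmax)
```

With `dilute_intermediate=True` the substrate balance becomes the quadratic
`µS² + (µK + Vmax − v_in)S − v_in·K = 0`, solved for its unique non-negative
root; a steady state then exists for any influx. `v_in ≥ Vmax` without
substrate dilution has no steady state; this is reported as
`feasible=False` (with the asymptotic flux `Vmax`) rather than raised, so
design scans can tabulate the infeasible region — in a scan the infeasible
region is exactly `v_in ≥ Vmax`.

Integration uses LSODA with `rtol=1e-8`, `atol=1e-10`. The substrate pool
relaxes at rate `λ = Vmax·K/(K+S*)²`, which becomes very slow near capacity;
tests that compare ODE endpoints against the closed form therefore integrate
for at least 40·max(1/λ, 1/µ) hours rather than a fixed horizon.

## From omics measurements to kinetic data

- µmol/gDCW → µM through the total cell volume per gram dry weight,
  `6.59e10 cells/gDCW × 66 fL/cell = 4.3494e-3 L/gDCW`; 1 µmol/gDCW =
  229.9 µM. Cell volume is a fixed literature value, not growth-rate
  dependent.
- fmol/µg protein → nM through `0.63 g protein/gDCW` over the same volume;
  1 fmol/µg = 144.8 nM.
- Production flux of a stable product: `flux = [P]·µ`, valid only under the
  steady-state, no-degradation assumption, which is recorded in the output
  provenance. Growth rates are paired with concentrations per replicate.
- Turnover number: `kcat = Vmax/([E]·3600)` in s⁻¹.

Replicates are kept as independent points and never averaged before
fitting. Measurements flagged below the limit of quantification are dropped
by default (policy `drop`) and listed in the provenance block;
`half_loq` substitution is available when a LOQ value is supplied.

## Parameter estimation

Point estimates minimise the unweighted sum of squared rate residuals of
`v = Vmax·S/(K+S)`. Positivity is enforced by optimising `ln Vmax, ln K`
(trust-region reflective with analytic Jacobian, tolerances 1e-12); results
are reported on the natural scale. The default start is
`Vmax₀ = 1.2·max(v)` and `K₀` = the substrate whose rate is closest to half
the maximum; on non-convergence, five starts with `K₀` log-spaced across the
substrate range are tried. The residual standard deviation uses `n − 2`
degrees of freedom. The parameter covariance is the usual
`s²·(JᵀJ)⁻¹` evaluated at the optimum on the natural scale.

Because the optimiser works in log space and the initial guess is built
from the data, the fit is exactly equivariant under unit-consistent
rescaling (scaling all S by c scales K̂ by c; scaling all rates scales
V̂max) and invariant to row order.

### Monte-Carlo uncertainty

Uncertainty follows a parametric resampling scheme: 1000 synthetic datasets
are formed by adding independent Gaussian noise — standard deviation equal
to the fit's residual sd — to the **fitted** rates; each is refit starting
from the point estimate; the mean, sd, relative sd and percentile
(2.5/97.5) 95% interval of each parameter are summarised from the
distribution. Refit failures are counted, reported and excluded. Resampled
rates are deliberately *not* truncated at zero: the noise model is plain
Gaussian, and truncation would bias the low-rate design points. Noiseless
input (zero residual sd, up to optimiser round-off) raises a
degenerate-noise error unless the caller supplies a noise floor. The seed
is always recorded; the default is 42.

### Identifiability

A parameter is declared non-identifiable when any of:

1. Monte-Carlo relative sd > 0.5 (configurable);
2. more than 2.5% of refits pile onto the internal optimiser bound;
3. the fit covariance is near-singular (condition number of JᵀJ > 1e8);
4. **saturation-range rule**: the Monte-Carlo median of K exceeds 1.5× the
   largest observed substrate concentration.

Rule 4 exists because the spread-based rules can be fooled in the
near-linear regime: when a noisy draw happens to place the point estimate
at small K, the Monte-Carlo world centred on that estimate is
self-consistently tight even though the true K lies far beyond the sampled
range. When half-saturation was never approached, the data constrain only
the efficiency Vmax/K, so *both* parameters are unbounded above and both
are flagged. For every non-identifiable parameter the 2.5th Monte-Carlo
percentile is reported as a finite lower limit — a convention of this
package; limits are meaningful precisely because the unidentifiable
direction runs upward.

## Synthetic strain panels

The generator emulates an engineered yeast collection: each strain has an
influx level (either given directly or as promoter × copy-number with a
linear per-copy strength), each replicate draws
`µ ~ Normal(0.40, 0.03)` truncated at zero, the noiseless steady state
comes from the pathway model, and measured concentrations get
multiplicative lognormal noise with CV 10%, mean-corrected so the expected
noisy value equals the truth. Concentrations span orders of magnitude and
must stay positive, which is why the noise is multiplicative. Below-LOQ
flags are set exactly when the noisy value falls under the configured
limit. True parameters live in a separate sidecar file so fitting code
cannot read them. Presets cover a partially saturating panel
(Vmax 849 µM/h, K 19 µM, substrate 0.12–20.78 µM ≈ 167-fold), a saturating
desaturase panel (168, 380, substrate 4–1641 µM), a second saturating panel
(309, 41), a deliberately unsaturated panel (13, 560, substrate truncated
to 4–100 µM), a 38-fold base panel, and the three-level design-scan grid
(Vmax ∈ {0.02, 0.4, 0.7} µM/h, K = 1 µM, v_in 0.01–0.4 µM/h).

What the generator does **not** emulate: batch structure in replicate
noise (a single CV is used), growth-rate feedback or toxicity at high
product levels, secretion/overflow losses, and measurement error models
specific to chromatography. Most importantly, it adds noise to the
substrate axis (errors in variables), which the rate-only Monte-Carlo
resampling does not model; the resulting 95% intervals cover the truth
substantially less often than nominal on full lognormal panels, and the
point estimates of K carry a mild attenuation bias. Passing recovery tests
therefore demonstrate calibration of the Monte-Carlo procedure *under its
own noise model* and approximate recovery under realistic panel noise —
not full frequentist calibration for real data.

## Problem sizes and numerical checks

- Closed form vs ODE: 100 random parameter sets, log-uniform over
  [1e-3, 1e3] (rates/concentrations) with influx at 1–90% of capacity;
  agreement to 1e-6 relative.
- Recovery: 100 seeded lognormal panels at the (849, 19) design point;
  median |relative error| is required to stay below 10% (Vmax) and
  20% (K).
- Interval calibration: 200 panels under the additive-Gaussian noise model
  (sd 40 µM/h) with 300 Monte-Carlo refits per panel; per-parameter
  coverage is required to fall in the 0.90–1.00 band. The library default
  of 1000 refits is used everywhere else; 300 keeps the 60 000-fit
  calibration run inexpensive and changes percentile endpoints by well
  under the interval width.
- Printed-value recoveries in the acceptance suite use medians over 100
  seeded panels per enzyme preset; the estimator's skewed distribution
  makes smaller-sample medians unstable.

## Known limitations

- The flux equation ignores degradation, secretion and further conversion
  of the product; it is wrong for intermediates with downstream consumers
  unless that consumption is measured separately.
- Homoscedastic unweighted fitting over rates spanning orders of magnitude
  lets the highest-rate strains dominate; a weighted scheme is deliberately
  out of scope.
- Substrate measurement error is not propagated (see above).
- The lower-limit convention (2.5th percentile) is tied to the Monte-Carlo
  noise level and should be read as "the data exclude smaller values at
  this noise level", not as a likelihood-profile bound.
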