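# invivokinetics

Estimation of **in vivo Michaelis–Menten enzyme parameters** from panels of
engineered strains, with Monte-Carlo uncertainty and identifiability
diagnostics.

## The problem

Classical enzymology measures V<sub>max</sub> and K<sub>M</sub> in a cuvette,
far from the crowded, regulated interior of a living cell. An alternative is
to measure kinetics *inside* cells: build a collection of strains that differ
only in the expression of the substrate-producing enzyme, so that each strain
settles at a different steady-state substrate concentration, then read off
one (substrate concentration, reaction rate) point per strain from omics
measurements. The canonical application is the carotenoid pathway in yeast —
GGPP synthase (CrtE) feeding phytoene synthase (CrtB) and, downstream,
phytoene desaturases (CrtI) — but the machinery is generic.

At metabolic steady state during exponential growth at rate µ, a stable end
product P accumulating only through synthesis obeys

```
v_synthesis = [P] · µ
```

so concentrations plus growth rates yield fluxes without isotope tracing.
Fitting the irreversible Michaelis–Menten law

```
v = Vmax_cell · [S] / (K½_cell + [S])
```

across the strain panel gives the in-cell analogues of V<sub>max</sub> and
K<sub>M</sub>, and dividing by an absolutely quantified enzyme concentration
gives the in-cell turnover number `kcat_cell = Vmax_cell / [E]`.

## What the package provides

- **`model`** — the design model: a pathway with constant influx `v_in`, a
  Michaelis–Menten conversion step, and first-order growth dilution of the
  product. Closed-form steady states (`S* = K·v_in/(Vmax − v_in)` for
  `v_in < Vmax`), stiff ODE time courses, and `design_scan` tables over
  enzyme levels × influxes to pick expression levels *before* cloning.
- **`quantify`** — unit conversions (µmol/gDCW → µM through
  6.59×10¹⁰ cells/gDCW and 66 fL/cell; fmol/µg protein → nM through
  0.63 g protein/gDCW), dilution fluxes, turnover numbers, and assembly of
  measurement tables into fit-ready datasets with below-LOQ handling.
- **`fitting`** — unweighted nonlinear least squares on a positivity-enforcing
  log parameterisation; parametric Monte-Carlo uncertainty (refit 1000
  Gaussian-noise resamples at the residual noise level); identifiability
  triage that reports finite **lower limits** instead of meaningless point
  estimates when the substrate range never approaches half-saturation.
- **`synthetic`** — seeded generators of realistic strain panels (growth rate
  0.40 ± 0.03 h⁻¹, 3 biological replicates, lognormal concentration noise)
  including presets shaped on published enzyme panels.
- **`report` / CLI** — an end-to-end `pipeline` producing byte-reproducible
  JSON reports, plus `generate`, `design-scan`, `quantify` and `fit`
  subcommands under the `invivokinetics` command.

## Worked example

```python
from invivokinetics import (reference_presets, generate_strain_panel,
                            build_dataset, fit_michaelis_menten,
                            monte_carlo_uncertainty, assess_identifiability)

cfg = reference_presets()["crtB_medium"]     # truth: Vmax=849 µM/h, K=19 µM
data = build_dataset(generate_strain_panel(cfg))
fit = assess_identifiability(monte_carlo_uncertainty(
    data, fit_michaelis_menten(data), n=1000, seed=42))
```

prints, via `examples/03_fit_enzyme_parameters.py`:

```
panel: 24 pairs, substrate 0.10-22.2 µM (226-fold)
vmax   :      903 ± 59  (rsd 7%), 95% CI [795, 1.03e+03]
k_half :     19.7 ± 2.2  (rsd 11%), 95% CI [15.6, 24.3]
identifiable: {'vmax': True, 'k_half': True}
```

The 24 replicate points span a ~200-fold substrate range; the fitted
`Vmax_cell` and `K½_cell` bracket the generating truth (849, 19) inside the
Monte-Carlo 95% intervals, with relative uncertainties around 7% and 11%.
With the enzyme at 42 nM the full pipeline additionally reports
`kcat_cell ≈ 5.9 s⁻¹` (≈ 6 s⁻¹). Contrast with
`examples/04_identifiability_triage.py`, where a panel whose substrate never
exceeds a fifth of K is triaged as non-identifiable and only lower limits
are reported.

See `examples/` for one short script per capability and `docs/methods.md`
for the modelling and statistical details.

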