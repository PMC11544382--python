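# fidashift

Flow-induced dispersion analysis (FIDA) of how the signaling lipid
sphingosine 1-phosphate (S1P) partitions between its plasma carriers —
serum albumin (HSA) and HDL particles — and how that partition, read out as
a hydrodynamic-radius shift, behaves as a sepsis-severity and outcome
marker.

The package is written for assay developers and computational biologists
who want to simulate, fit, and statistically analyze FIDA measurements of
ligand-carrier systems without access to instrument software or patient
plasma: every stage, from the Taylor-Aris dispersion physics to the
clinical cohort table, can be generated synthetically and pushed through
the same analysis code that would process real exports.

## The measurement model

In a FIDA experiment a fluorescent indicator plug (here FITC-labelled S1P)
is mobilized through a thin capillary under laminar flow. Taylor-Aris
dispersion makes the detected peak's temporal variance a direct function of
the indicator's diffusion coefficient,

    sigma_t^2 = r_c^2 * t_R / (24 D),

and the Stokes-Einstein relation converts D to an apparent hydrodynamic
radius R_h = k_B T / (6 pi eta D). Binding to a carrier increases the
apparent size. With the indicator far below the carriers' site
concentrations, a 1:1 fast-exchange isotherm applies,

    r_app = (1 - f_b) r_free + f_b r_complex,   f_b = C / (K_D + C),

and with two competing carriers the free fraction generalizes to
f_free = 1 / (1 + C_HSA/K_HSA + beta C_HDL/K_HDL). The two assay modes
differ in beta: the capillary-mix method (CapMix) mixes indicator and
analyte in-capillary, leaving no time for the slow S1P/HDL association
(beta = 0 by default), while the complex-dissociation method (CapDis)
pre-equilibrates them (beta = 1). Subtracting the two per-sample radii,

    Delta R_h = R_h(CapDis) - R_h(CapMix),

cancels the shared HSA contribution and isolates the indicator's shift
toward HDL — the carrier-shift statistic the cohort analysis is built on.

Modules: `physics` (dispersion closed forms, Taylorgram simulator, Langevin
oracle), `fitting` (Gaussian single-/two-species fits, PDI, S/N),
`binding` (isotherms, competition, K_D fitting, unit conversions),
`carrier_shift` (Delta R_h, SOFA bins, Mann-Whitney/Spearman, outcome
association), `synthetic_data` (cohort generator, LC-MS/MS emulation),
`io_utils`/`cli`/`pipeline` (formats, configuration, command line).

## Worked example

```python
import numpy as np
from fidashift import (CapillarySetup, Species, capmix_protocol,
                       simulate_taylorgram, fit_single_species,
                       BindingCurve, isotherm_rapp, fit_binding_curve,
                       mass_to_molar_kd, generate_cohort, analyze_cohort)
from fidashift.physics import noise_sd_for_snr

# 1. simulate a plasma-like CapMix Taylorgram of a 3.5 nm S1P/HSA complex
cap, proto = CapillarySetup(), capmix_protocol()
mix = [Species(r_h=3.5, amplitude_fraction=1.0)]
noise = noise_sd_for_snr(mix, proto, cap, snr=100)
tg = simulate_taylorgram(mix, proto, cap, baseline=(1.0, 0.002),
                         noise_sd=noise, seed=11)
fit = fit_single_species(tg, cap)
print(fit.r_h, fit.snr)        # 3.512 nm, S/N 103.4

# 2. fit a titration of the indicator against HSA (K_D in mg/mL)
rng = np.random.default_rng(0)
conc = np.repeat([0, .005, .01, .02, .04, .08, .15, .3, .6, 1.2, 2, 4], 3)
r = isotherm_rapp(conc, 0.020, 0.9, 3.5) * (1 + 0.01 * rng.standard_normal(36))
bf = fit_binding_curve(BindingCurve(conc, r, unit="mg/mL"))
print(bf.k_d)                                  # 0.0206 mg/mL (truth 0.020)
print(mass_to_molar_kd(0.020, 66_500) * 1e9)   # 300.8 nM

# 3. generate a synthetic 77-sample cohort and analyze it
cohort = generate_cohort(seed=1)
res = analyze_cohort(cohort)
print(res.group_summary["delta_rh_mean"].round(3))
# control 1.368, trauma 2.238, sepsis 2.167, septic_shock 1.699
```

The Delta R_h means show the carrier shift: all patient groups sit above
the healthy controls (control vs sepsis: Mann-Whitney p = 7e-8 on this
seed), while the septic-shock group is the most heterogeneous (SD 0.64 nm
vs ~0.2 nm elsewhere) because it contains a low-HDL-complex subgroup. In
the same run's outcome analysis, septic-shock survivors had a median
R_h(CapDis) of 4.61 nm against 3.30 nm in the deceased (exact p = 0.0005),
whereas CRP did not separate survival (p = 0.26) despite separating
ventilation (p = 0.042) — the diagnostic contrast the carrier-shift marker
is designed to expose.

A command-line surface wraps the same functions:

```
fidashift synth --seed 1 --out cohort.csv
fidashift simulate --method capmix --rh 3.5 --noise-sd 0.02 --out trace.csv
fidashift fit --in trace.csv --method single --out fit.json
fidashift binding-fit --in curve.csv --out bind.json
fidashift cohort run --in cohort.csv --out report/
fidashift pipeline --seed 1 --out run1/ --skip-taylorgrams
```

File schemas are documented in `FORMATS.md`, the scientific and numerical
choices in `docs/methods.md`.

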