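# Methods

## Dispersion physics

The simulator and the fits share one analytic model. A solute plug in
laminar Poiseuille flow through a capillary of inner radius `r_c` disperses
axially with effective dispersion coefficient `K = r_c^2 u^2 / (48 D)`;
after the residence time `t_R = L / u` the detected peak is near-Gaussian with
temporal variance `sigma_t^2 = r_c^2 t_R / (24 D)`. Axial molecular
diffusion is neglected: for the sizes this assay measures (0.9–5.5 nm) the
Peclet number in the default geometry is above 10^3, so the omitted term is
orders of magnitude below the Taylor term. Validity is guarded by
`taylor_validity`, which checks the standard criteria `tau = D t_R / r_c^2
>= 1.4` (radial equilibration) and `Pe = u r_c / D >= 69`, both inclusive
and configurable.

The closed form is verified against an independent brute-force oracle
(`langevin_temporal_variance`): 10^4 random walkers start uniformly over the
cross-section, diffuse transversely with reflection at the wall, and are
advected by the parabolic profile; the empirical variance of their axial
positions divided by `u^2` reproduces `sigma_t^2` within a few percent at
`tau >= 1.4` (the residual difference is finite-time correlation plus Monte
Carlo error).

Capillary geometry is not published for the instrument; the defaults
`r_c = 37.5 um`, `L = 0.84 m`, `t_R = 120 s` are chosen to be typical of
commercial FIDA capillaries, put all species of interest comfortably inside
the Taylor regime, and are configurable everywhere. Temperature defaults to
310.15 K (the capillary is thermostatted at 37 °C) with the viscosity of
water at that temperature, 6.913e-4 Pa s. Because the instrument's internal
calibration is unknown, no claim is made that simulated traces match vendor
software numerically; all recovery tests close the loop against this
package's own simulator.

## Taylorgram simulation and noise

`simulate_taylorgram` renders each species as a Gaussian centred on the
shared `t_R` with width from its diffusion coefficient; the summed area is
proportional to the indicator concentration (50 nM for the capillary-mix
protocol, 500 nM for complex dissociation), split by amplitude fractions.
Noise is additive white Gaussian plus a linear baseline (offset + drift),
which reproduces the slight drift real traces show and supports the S/N
definition below. Injection-plug width, photobleaching and detector
nonlinearity are out of scope. Traces are sampled at 20 Hz over `2 t_R`
(4801 points), enough to resolve the narrowest peak (sigma ≈ 4.6 s at
1 nm) by two orders of magnitude.

## Peak fitting

Fits are unweighted nonlinear least squares (`scipy.optimize.least_squares`)
of one or two shared-centre Gaussians, after subtracting a straight line
fitted to the regions farther than 4 initial widths from the apex (the
initial width comes from FWHM/2.3548 on a detrended copy; a trace without a
discernible peak is treated as all baseline). Widths are parameterized as
`log sigma`, so negative widths cannot occur; three jittered restarts
(seeded) guard against local minima and the lowest RSS wins.
Non-convergence sets a flag rather than raising.

Signal-to-noise is the corrected peak amplitude over the SD of the baseline
region well clear of the peak (6 initial widths); a noise-free trace
reports infinite S/N with the interpretable flag set, and S/N >= 30 marks a
trace interpretable.

The two-species fit shares the centre and resolves two widths; the
smaller-radius component is interpreted as free indicator, optionally
pinned to a known free radius. Two safeguards prevent over-fitting noise:
components whose widths differ by less than 5% are unresolvable and trigger
a degenerate flag with fallback to the single-species description, and a
component whose fitted amplitude is below 3 baseline-noise SDs is below the
detection limit and treated the same way. The two-species result is also
never reported when its RSS exceeds the single-species RSS. With these
rules the two-species fit of a genuinely monodisperse trace collapses to
one species (PDI 0) or to a near-zero spurious fraction, keeping PDI far
below the 0.1 level observed for homogeneous complexes.

The polydispersity index is the area-weighted relative variance of the
fitted radii, `PDI = sum_i f_i (r_i - rbar)^2 / rbar^2` — the DLS-style
convention implied by the field's "PDI < 0.5 is monodisperse" language;
the vendor's exact definition is unpublished, so agreement with instrument
PDI values is not claimed. Diffusion coefficients come from inverting the
Taylor variance at the fitted `(sigma_t, t_R)` and radii from
Stokes-Einstein.

## Binding models

All binding uses the 1:1 fast-exchange population-weighted radius with the
indicator far below site concentrations (50–500 nM indicator against
>= ug/mL-scale carriers), so indicator depletion is ignored. Titration fits
run on `log K_D` with inverse replicate-variance weights when replicates
carry information; standard errors come from the Gauss-Newton covariance. A
fitted K_D more than 3x beyond the highest tested concentration is flagged
as extrapolated, and a flat response is a flagged failure with no K_D.

The two-carrier competition model assigns the capillary-mix method an HDL
attenuation `alpha` (default 0: no S1P/HDL complex forms within the
in-capillary mixing window, reflecting the slow association kinetics of the
lipoprotein) and the complex-dissociation method `beta = 1`. Reference
radii default to 0.9 nm (free S1P-FITC, a ~0.77 kDa conjugate), 3.5 nm
(albumin complex) and 5.5 nm (HDL-particle complex); molar masses default
to 66.5 kDa (HSA) and 21 kDa (ApoM), all configurable.

## Cohort statistics

`Delta R_h = R_h(CapDis) - R_h(CapMix)`, so a shift toward HDL is positive;
a configuration flag flips the sign for users who prefer the opposite
convention. Group contrasts use the two-sided Mann-Whitney U test: exact
null when min(n) <= 8 and the pooled data are tie-free, tie-corrected
normal approximation otherwise, and all-tied input returns p = 1 with a
warning. The exact branch is validated against brute-force enumeration of
every label assignment for group sizes up to 6. Correlations are Spearman
with average ranks and pairwise deletion (each analysis reports its own n);
no multiple-testing correction is applied — p-values are per contrast.
SOFA reclassification uses closed bins <=3, 4–7, >=8, with controls kept as
their own category regardless of any SOFA field.

Outcome association restricts to the severe subgroup (septic-shock group or
SOFA >= 8 bin) and compares R_h(CapDis) and CRP between ventilated /
non-ventilated and surviving / deceased patients, reporting direction and
p; comparisons with fewer than 3 samples per class are skipped and logged.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised; patient plasma is not available, so these are modelling choices,
stated once here:

- **Group profiles.** n = 14 controls, 11 trauma, 36 sepsis, 16 septic
  shock. HSA medians 43/25/22/17 g/L and HDL medians 61/61/34/13 mg/dL
  (trauma keeps the control HDL level); lognormal dispersion sigma 0.15
  (HSA) and 0.25 (HDL), chosen as typical clinical-analyte spreads since
  only medians are known. SOFA scores are rounded lognormals matched to
  median (IQR): trauma 4 (3–5), sepsis 4 (2–6), shock 8 (7–11). HDL
  cholesterol converts to HDL protein at 122 (mg/dL)/(mg/mL), putting a
  healthy 61 mg/dL at ~0.5 mg/mL HDL protein.
- **Latent partition.** Each patient draws a latent HDL-bound S1P fraction
  from a Beta distribution (concentration 40) around the group median:
  0.55 control, 0.80 trauma, 0.75 sepsis; septic shock is a 65/35 mixture
  of a 0.70 component and a 0.20 "low-complex" component — the subgroup
  with very low HDL-complex formation.
- **Latent radii.** Both methods' radii come from the competitive
  two-carrier model on the 10%-plasma concentrations. The apparent HSA
  affinity in plasma is set to 1.0 mg/mL (weaker than the 0.020 mg/mL
  measured against purified albumin) because endogenous S1P and fatty acids
  compete for albumin's binding sites; this places 10% plasma on the
  responsive part of the isotherm so the capillary-mix radius tracks
  albumin concentration. The per-sample HDL term is inverted from the
  latent fraction (g = f (1+h)/(1-f)), making the complex-dissociation
  radius carry the carrier-shift signal. Observed radii add 1.5%
  multiplicative Gaussian noise — bracketing the assay's 0.4–1.6%
  intra-/interday precision.
- **Outcomes.** Ventilation and death are Bernoulli draws with logistic
  links on the latent CapDis radius (slopes 1.2 and 4.0 per nm, midpoints
  4.1 and 3.9 nm): small HDL complexes raise both risks, with death coupled
  more steeply so the deceased concentrate in the low-complex subgroup.
  CRP is lognormal conditioned on ventilation only (medians 160 vs 105
  mg/L, sigma 0.45) — by construction CRP carries ventilation information
  but no survival information beyond the indirect path through the shared
  latent, reproducing a marker that flags disease activity but not
  outcome. Controls carry no SOFA, outcomes, or CRP.
- **LC-MS/MS.** Total plasma S1P (lognormal medians 400/480/420/300 pmol
  per extraction) splits over HDL / HSA / other lipoproteins (other = 8%);
  each fraction is quantified by isotope dilution against 100 pmol of
  C17-S1P through a linear standard curve, with fraction-specific recovery
  (0.95 HSA, 0.85 HDL) and 20% CV multiplicative noise — deliberately
  noisier than the FIDA readout, as processed-sample lipid quantification
  is. Reported fractions are relative to the summed quantified S1P, so
  HSA + HDL fractions never exceed 1. 15% of samples lose their LC-MS
  readout to emulate missingness and exercise pairwise deletion.

What the generator does **not** emulate: carrier modifications (oxidation,
post-translational changes) that alter binding beyond concentration,
serum-versus-plasma matrix differences (measured to be negligible),
chromatographic peak shapes, and any absolute calibration of the
instrument. Passing cohort tests therefore demonstrates that the pipeline
recovers the structure the generator encodes — directional group ordering,
subgroup enrichment, marker contrasts — not that real plasma would produce
these numbers. One consequence of the equilibrium model: with albumin near
saturation the capillary-mix radius varies only weakly across groups, so
its group contrasts are less separated than the complex-dissociation ones.

## Numerical choices

Optimizer tolerances 1e-12 (ftol/xtol), max 2000 function evaluations,
3 seeded restarts with 5% jitter. The Langevin oracle uses dt = 0.02 s so
the transverse step (~40 nm) is far below the capillary radius. Exact
Mann-Whitney switches to the normal approximation above min(n) = 8 or in
the presence of ties. Degenerate inputs are handled explicitly: empty
mixtures, flat titrations, all-tied samples, single-class outcomes,
negative quantifications (clipped to 0 and flagged), zero internal-standard
areas (error).

## Known limitations

- The effective in-plasma affinities and all outcome-coupling slopes are
  free parameters of the generator, not measured quantities.
- The PDI convention and the instrument's multi-species model are not the
  vendor's; measured free-indicator percentages from instrument software
  are not reproduction targets.
- N-species deconvolution beyond two components, kinetic (k_on/k_off)
  estimation, survival-time modelling and ROC benchmarking are out of
  scope.
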