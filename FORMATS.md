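# File formats

All files are UTF-8 text with `.` as decimal separator.

## Taylorgram CSV

Header required, exactly:

```
time_s,signal_au
0.0,0.1234
0.05,0.1239
...
```

- `time_s`: detector time in seconds, strictly increasing, uniformly sampled
  (1e-9 relative tolerance), at least 50 rows.
- `signal_au`: fluorescence in arbitrary units.

Parse errors report the offending line number. Acquisition metadata
(capillary geometry, protocol, noise model, seed) travels in the run
configuration file, not in the trace.

## Binding-curve CSV

```
conc,unit,r_app_nm,replicate
0.0,mg/mL,0.901,1
0.005,mg/mL,1.42,1
...
```

- `conc`: analyte concentration; repeated values are replicates.
- `unit`: one unit per file (`mg/mL` or `ug/mL`); carried into the fitted
  K_D.
- `r_app_nm`: apparent hydrodynamic radius in nm.
- `replicate`: informative only.

## Cohort CSV

One row per sample. Required columns: `sample_id`, `group` (one of
`control`, `trauma`, `sepsis`, `septic_shock`), `r_capmix`, `r_capdis`
(nm). Optional: `sofa` (integer, patients only), `ventilated`, `survived`
(booleans), `crp` (mg/L), `lcms_frac_hsa`, `lcms_frac_hdl` (fractions in
[0, 1]). Missing values are empty cells; every analysis deletes missing
data pairwise and reports its own n. Synthetic cohorts additionally carry
the generator's latent columns (`*_latent`, `s1p_frac_hdl_true`,
`total_s1p_pmol`, `hsa_g_l`, `hdl_mg_dl`, `delta_rh`).

## Run configuration (YAML)

Produced/consumed by `fidashift.io_utils.save_config` / `load_config`;
round-trips losslessly. Top-level keys: `seed`, `capillary`, `fitting`,
`generator`, `profiles`, `hdl_positive_delta`, `simulate_taylorgrams`,
`provenance` (a note per default saying whether it is a protocol constant
or a chosen modelling default).

## Outputs

- `fit.json` / `bind.json`: flat key-value fit reports (units in key names).
- `cohort run` / `pipeline` output directory: `group_summary.tsv`,
  `sofa_summary.tsv` (per-group n/mean/SD of `r_capmix`, `r_capdis`,
  `delta_rh`), `report.json` (full machine-readable analysis), and for
  `pipeline` also `cohort.csv` and `pipeline.log`.
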