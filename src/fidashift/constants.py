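"""Physical constants and assay-level defaults.

All radii are in nm, diffusion coefficients in m^2/s, concentrations in the
assay-native mass units (mg/mL for carrier proteins, nM for the fluorescent
indicator) unless a function states otherwise.
"""

#: Boltzmann constant, J/K (exact, 2019 SI).
K_B = 1.380649e-23

#: Default capillary temperature, K. The capillary is thermostatted at 37 C
#: during the measurement.
T_CAPILLARY = 310.15

#: Dynamic viscosity of water at 37 C, Pa*s (CRC handbook interpolation).
ETA_WATER_37C = 6.913e-4

#: Molar mass of human serum albumin, g/mol.
HSA_MOLAR_MASS = 66_500.0

#: Molar mass of apolipoprotein M, g/mol.
APOM_MOLAR_MASS = 21_000.0

#: Typical ApoM content of HDL particles, mg ApoM per g HDL protein.
APOM_MG_PER_G_HDL = 30.0

#: Hydrodynamic radius of free S1P-FITC (a ~0.77 kDa lysolipid-fluorophore
#: conjugate), nm. Small-molecule scale; configurable everywhere it is used.
R_H_FREE_INDICATOR = 0.9

#: Hydrodynamic radius of the S1P-FITC/HSA complex, nm (monomeric albumin).
R_H_HSA_COMPLEX = 3.5

#: Hydrodynamic radius of the S1P-FITC/HDL complex, nm (HDL particle scale).
R_H_HDL_COMPLEX = 5.5

#: Dissociation constant of S1P-FITC binding to HSA (capillary-mix method),
#: mg/mL (= 20 ug/mL).
KD_HSA_MG_PER_ML = 0.020

#: Dissociation constant of S1P-FITC binding to HDL protein
#: (complex-dissociation method), mg/mL.
KD_HDL_MG_PER_ML = 1.25

#: Indicator concentrations of the two methods, nM.
INDICATOR_CAPMIX_NM = 50.0
INDICATOR_CAPDIS_NM = 500.0

#: Conversion from clinical HDL cholesterol (mg/dL) to HDL protein (mg/mL).
#: Chosen so that a healthy 61 mg/dL corresponds to ~0.5 mg/mL HDL protein,
#: the plasma HDL protein content quoted for healthy donors.
HDL_CHOL_MG_DL_PER_PROTEIN_MG_ML = 122.0
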