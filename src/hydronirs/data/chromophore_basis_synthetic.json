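{
 "name": "chromophore_basis_synthetic",
 "provenance": "Synthetic basis: PCHIP interpolation of literature-informed anchor values for HbO2/Hb molar extinction, pure water and lipid absorption; melanin modelled as a lambda^-3.48 power law (0.5 mm^-1 at 800 nm per unit fraction). Constructed for this package; not a verbatim copy of any published compilation.",
 "units": {
  "eps_hbo2_mm1_per_uM": "mm^-1 per uM (ln-based Beer law)",
  "eps_hb_mm1_per_uM": "mm^-1 per uM",
  "mua_water_mm1": "mm^-1 at volume fraction 1",
  "mua_lipid_mm1": "mm^-1 at volume fraction 1",
  "mua_melanin_mm1": "mm^-1 at fraction 1"
 },
 "grid_nm": [
  700.0,
  1000.0,
  2.0
 ]
}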