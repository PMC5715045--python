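# Companion configuration for the packaged C. necator H16 central-carbon
# model: metabolite roles, symmetric pools, and the three labelling-study
# conditions.  Uptake fluxes are the biomass-specific rates (g L-1 OD-1 h-1)
# converted to mmol/g DW/h with a configurable biomass density
# (g DW per litre per OD600 unit).  Precursor demands ("demands") are a
# uniform placeholder drain per proteinogenic amino acid, scaled per
# condition with growth.
co2: CO2
symmetric: [SUC, FUM]
substrates: [FRUx, GLYCx]
biomass_density_gdw_per_l_od: 0.4
conditions:
  hetero_fructose:
    substrate: FRUx
    tracer: "[1-13C]fructose"
    tracer_positions: [1]
    substrate_carbons: 6
    substrate_molar_mass: 180.16
    substrate_conc0_g_l: 4.0
    mu_h: 0.254
    uptake_g_l_od_h: 0.189
    measured: {upt_fru: 2.623, upt_glyc: 0.0}
    demands: 0.05
  hetero_glycerol:
    substrate: GLYCx
    tracer: "[1,2-13C]glycerol"
    tracer_positions: [1, 2]
    substrate_carbons: 3
    substrate_molar_mass: 92.09
    substrate_conc0_g_l: 10.0
    mu_h: 0.173
    uptake_g_l_od_h: 0.023
    measured: {upt_fru: 0.0, upt_glyc: 0.624}
    demands: 0.012
  mixo_glycerol_co2:
    substrate: GLYCx
    tracer: "[1,2-13C]glycerol"
    tracer_positions: [1, 2]
    substrate_carbons: 3
    substrate_molar_mass: 92.09
    substrate_conc0_g_l: 10.0
    mu_h: 0.23
    uptake_g_l_od_h: 0.055
    measured: {upt_fru: 0.0, upt_glyc: 1.493}
    demands: 0.03
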