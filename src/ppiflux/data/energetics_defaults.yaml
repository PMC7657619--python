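# Default constants of the PP_i / ATP budget, one flat mapping.
# Each value is a literature- or measurement-derived constant of the
# carbon-limited C. thermocellum reference condition; override any of
# them per run (CLI options or EnergeticsDefaults.replace).

biomass_yield: 0.16          # g cells per g cellobiose, observed
anabolic_cellobiose: 3.7     # mmol cellobiose to build 1 g cells (network accounting)
unaccounted_fraction: 0.16   # 1 - carbon recovery/100 (missing carbon)
ppdk_fraction: 0.6666666666666666  # share of PEP->pyruvate flux via PPDK (13C labeling)
pfk_ppi_per_cellobiose: 2.0  # one PP_i per hexose at PP_i-PFK
pep_per_cellobiose: 4.0      # two PEP per hexose
anabolic_ppi_credit: 11.0    # mmol PP_i generated in anabolism per g cells
base_atp_requirement: 34.7   # mmol ATP per g cells, biosynthetic accounting
protein_fraction: 0.524      # g protein per g cells in that accounting
residue_mass: 110.0          # mean amino-acid residue mass in protein, g/mol
cellobiose_mmol_mass: 0.3423 # g per mmol cellobiose
carbon_fraction: 0.45        # g C per g cells
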