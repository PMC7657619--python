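# Published specific fluxes (mmol per g cell N per h; amino acid and
# protein rows mg per g cell N per h) for wild-type carbon-limited,
# wild-type nitrogen-limited (0.15 g urea/liter) and PTA-deletion
# cultures.  Only the carbon-limited column has its full underlying
# concentration table packaged; the other columns serve for fold-change
# ratios.  flag values:
#   irreconcilable - printed value cannot be re-derived from the
#                    packaged concentrations under any molar-mass
#                    convention; excluded from validation.
#   ratios_only    - underlying concentrations unavailable; only ratios
#                    to the carbon-limited column are meaningful.
quantity,units,carbon_limited,nitrogen_limited_015_urea,pta_mutant,flag
cell_nitrogen,mg N/liter,102.0,40.4,71.8,
cell_carbon,mg C/liter,337.3,183.3,259.9,
q_cellobiose,mmol/g N/h,4.66,9.32,6.61,irreconcilable
q_acetate,mmol/g N/h,17.34,30.36,0.76,
q_ethanol,mmol/g N/h,14.89,16.35,25.62,
q_formate,mmol/g N/h,5.15,7.97,1.66,
q_lactate,mmol/g N/h,0.38,3.32,1.39,
q_excreted_pyruvate,mmol/g N/h,0.17,8.56,18.19,
q_total_pyruvate,mmol/g N/h,33.03,63.88,51.08,
q_valine,mmol/g N/h,0.13,2.64,2.56,
q_excreted_amino_acids,mg/g N/h,89.04,579.64,474.60,
q_supernatant_protein,mg/g N/h,101.42,60.04,51.67,
q_nitrogen_uptake,mmol/g N/h,9.75,14.26,12.89,
carbon_recovery,%,81.8,70.6,79.1,ratios_only
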