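# organism = Clostridium thermocellum
# dilution_rate_per_h = 0.1
# ph = 7.0
# temperature_c = 55
# declared_amino_acid_carbon_mg_per_l = 40.5
# declared_amino_acid_nitrogen_mg_per_l = 20.6
species,concentration_mg_per_l,role
cellobiose,4757.2,feed
ammonium_chloride,2000.0,feed
cellobiose,ND,residual
cell_carbon,337.3,cell_c
cell_nitrogen,102.0,cell_n
acetate,1062.4,product
ethanol,699.6,product
lactate,35.3,product
formate,241.8,product
glucose,20.2,product
pyruvate,15.4,product
isobutanol,25.3,product
supernatant_protein,103.5,protein
alanine,15.0,amino_acid
asparagine,0.5,amino_acid
aspartic_acid,1.7,amino_acid
glutamic_acid,30.0,amino_acid
glutamine,0.3,amino_acid
histidine,0.0,amino_acid
isoleucine,4.0,amino_acid
leucine,3.0,amino_acid
lysine,6.5,amino_acid
methionine,0.0,amino_acid
phenylalanine,1.0,amino_acid
proline,4.3,amino_acid
serine,4.6,amino_acid
threonine,4.0,amino_acid
tryptophan,0.3,amino_acid
tyrosine,0.6,amino_acid
valine,15.0,amino_acid
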