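# organism = Thermoanaerobacterium saccharolyticum
# dilution_rate_per_h = 0.1
# ph = 6.2
# temperature_c = 55
# declared_amino_acid_carbon_mg_per_l = 45.0
# declared_amino_acid_nitrogen_mg_per_l = 23.4
species,concentration_mg_per_l,role
cellobiose,4755.2,feed
ammonium_chloride,2000.0,feed
cellobiose,ND,residual
cell_carbon,129.2,cell_c
cell_nitrogen,39.3,cell_n
acetate,47.6,product
ethanol,1876.4,product
lactate,129.8,product
formate,12.3,product
glucose,3.8,product
pyruvate,7.6,product
isobutanol,ND,product
supernatant_protein,95.4,protein
alanine,38.5,amino_acid
asparagine,0.2,amino_acid
aspartic_acid,6.4,amino_acid
glutamic_acid,28.7,amino_acid
glutamine,3.1,amino_acid
histidine,0.0,amino_acid
isoleucine,1.3,amino_acid
leucine,1.9,amino_acid
lysine,2.9,amino_acid
methionine,0.2,amino_acid
phenylalanine,0.0,amino_acid
proline,5.1,amino_acid
serine,3.1,amino_acid
threonine,16.6,amino_acid
tryptophan,0.0,amino_acid
tyrosine,0.1,amino_acid
valine,2.6,amino_acid
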