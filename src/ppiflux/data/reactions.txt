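# Built-in pathway library.
# reaction <name>: <equation>    coefficients integer or rational, "1" omitted
# combo <name> = r1 + r2 - r3    "-" runs a reaction in reverse; "k*r" scales
#
# Names ending in _as_printed are verbatim schematic forms that are
# deliberately unbalanced on the phosphate ledger (see module docs).

# -- PEP -> pyruvate and the adenylate system
reaction ppdk: PEP + AMP + PPi -> pyruvate + ATP + Pi
reaction adenylate_kinase: 2 ADP -> AMP + ATP
reaction ppi_generator: ATP + Pi -> ADP + PPi
reaction pp_glycolysis_net: glucose + 5 ADP + 3 PPi -> 2 pyruvate + 5 ATP + Pi
reaction ppdk_in_vivo_as_printed: PEP + AMP + PPi -> pyruvate + Pi

# -- malate shunt (PEP carboxykinase, malate dehydrogenase, NADP malic enzyme)
reaction pep_carboxykinase: PEP + CO2 + GDP -> OAA + GTP
reaction malate_dehydrogenase: OAA + NADH -> malate + NAD
reaction malic_enzyme: malate + NADP -> pyruvate + CO2 + NADPH

# -- electron bifurcation
reaction nfnab: Fd_red + NADH + 2 NADP -> Fd_ox + NAD + 2 NADPH

# -- peptide-bond formation (tRNA charging + ribosomal elongation)
reaction trna_charging: aa1 + aa2 + 2 GTP + ATP -> aa1-aa2 + 2 GDP + 2 Pi + AMP + PPi
reaction soluble_ppase: PPi + H2O -> 2 Pi

# -- transaldolase-free pentose-phosphate cycle
reaction ppi_pfk_f6p: 2 F6P + 2 PPi -> 2 FBP + 2 Pi
reaction aldolase_fbp: 2 FBP -> 4 C3P
reaction transketolase_1: F6P + C3P -> C5P + C4P
reaction aldolase_sbp: C4P + C3P -> SBP
reaction ppi_pfk_sbp_reverse: SBP + Pi -> C7P + PPi
reaction transketolase_2: C7P + C3P -> 2 C5P
reaction pentose_net_as_printed: 3 C6P + PPi -> 3 C5P + C3P

# -- glycogen cycle (ADP-glucose pyrophosphorylase route), overall reaction
reaction glycogen_cycle_net: ATP + Pi -> ADP + PPi

combo ppdk_plus_ak = ppdk + adenylate_kinase
combo ppdk_in_vivo = ppdk + ppi_generator + adenylate_kinase
combo malate_shunt = pep_carboxykinase + malate_dehydrogenase + malic_enzyme
combo trna_charging_ecoli = trna_charging + soluble_ppase - adenylate_kinase
combo trna_charging_no_ppase = trna_charging + ppdk
combo pentose_no_transaldolase = ppi_pfk_f6p + aldolase_fbp + transketolase_1 + aldolase_sbp + ppi_pfk_sbp_reverse + transketolase_2
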