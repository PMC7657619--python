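# Enzyme activities in core metabolism of cellobiose-limited cultures
# at D = 0.1/h (umol/mg cell-extract protein/min, mean and SD).
# Data-only fixture: no computation in this package consumes it.
# "<0.01" means below the assay detection limit.
enzyme,cofactor,cthermocellum,cthermocellum_sd,tsaccharolyticum,tsaccharolyticum_sd
Glucokinase,GTP,0.71,0.11,0.07,0.02
Glucokinase,ATP,0.06,0.00,0.84,0.05
Glucokinase,PEP,<0.01,,<0.01,
Phosphofructokinase,PPi,1.20,0.28,<0.01,
Phosphofructokinase,ATP,<0.01,,0.55,0.05
Phosphoglycerate kinase,GDP,2.37,0.14,0.35,0.02
Phosphoglycerate kinase,ADP,3.21,0.28,6.70,1.37
GAP dehydrogenase,NAD,3.86,0.57,11.68,2.68
GAP dehydrogenase,NADP,<0.01,,0.07,0.02
PEP carboxykinase,ADP,0.16,0.03,0.49,0.02
PEP carboxykinase,GDP,4.80,0.26,0.11,0.04
PEP carboxykinase,Pi,<0.01,,<0.01,
Pyruvate kinase,ADP,<0.01,,0.65,0.04
Pyruvate phosphate dikinase,AMP+PPi,0.19,0.03,0.86,0.09
Malate dehydrogenase,NADH,3.79,0.85,<0.01,
Malate dehydrogenase,NADPH,0.24,0.05,0.07,0.01
Malic enzyme,NAD,0.05,0.01,0.06,0.01
Malic enzyme,NADP,2.78,0.44,0.07,0.01
Glucose-6-phosphate dehydrogenase,NADP,<0.01,,0.03,0.01
6-phosphogluconate dehydrogenase,NADP,<0.01,,0.05,0.01
Isocitrate dehydrogenase,NAD,<0.01,,<0.01,
Isocitrate dehydrogenase,NADP,1.05,0.07,0.91,0.19
Glutamate dehydrogenase,NAD,<0.01,,<0.01,
Glutamate dehydrogenase,NADP,2.34,0.35,<0.01,
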