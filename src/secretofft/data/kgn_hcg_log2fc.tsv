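protein	log2fc
Coatomer subunit epsilon	1.571257
Alpha-N-acetylglucosaminidase	1.927359
Cation-independent mannose-6-phosphate receptor	1.89474
Peroxidasin homolog	2.054181
Gamma-glutamyl hydrolase	1.580536
Protein CutA	3.314857
Glia maturation factor beta	2.227123
Apolipoprotein E	2.208065
Heat shock 70 kDa protein 4	2.532013
Collagen alpha-1(VIII) chain	1.578419
Microtubule-associated protein 4	1.601187
Cell growth regulator with EF hand domain protein 1	2.059668
Serine/threonine-protein phosphatase CPPED1	3.221587
Matrilin-2	1.655928
Beta-hexosaminidase subunit beta	1.663284
Clathrin heavy chain 1	1.599876
Complement factor B	2.113103
Myosin-9	2.010879
Prothrombin	1.582737
Pigment epithelium-derived factor	1.606319
Hemicentin-1	1.586922
DNA damage-binding protein 1	3.040665
Fatty acid synthase	3.919236
Keratin, type II cytoskeletal 2 epidermal	3.001855
Hemopexin	1.590041
Actin-related protein 2	-2.23692
Purine nucleoside phosphorylase	-1.60307
Destrin	-2.79295
Zyxin	-1.90296
Puromycin-sensitive aminopeptidase	-1.52848
Xaa-Pro dipeptidase	-1.90618
Inter-alpha-trypsin inhibitor heavy chain H1	-2.78443
Proliferating cell nuclear antigen	-2.08102
Neuropilin-2	-3.82035
Protein disulfide-isomerase A4	-2.27668
Cytochrome c	-1.82228
Peroxiredoxin-6	-1.74853
Target of Nesh-SH3	-1.97661
Adenylyl cyclase-associated protein 1	-1.50756
60S ribosomal protein L12	-1.81288
Di-N-acetylchitobiase	-3.48137
Heat shock protein HSP 90-alpha	-3.81346
Plectin	-3.23123
CD9 antigen	-1.59051
Keratin, type I cytoskeletal 18	-1.63406
Endoplasmin	-2.15751
Stathmin	-2.51708
Isoform 3 of Tropomyosin alpha-1 chain	-1.55216
Vinculin	-2.46508
Alpha-actinin-1	-1.7867
Tubulin beta chain	-2.59979
Keratin, type II cytoskeletal 1	-2.55098
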