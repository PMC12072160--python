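protein	log2fc
Alpha-N-acetylglucosaminidase	1.785251
F-actin-capping protein subunit alpha-2	1.873705
Protein CutA	3.283473
Heat shock 70 kDa protein 4	1.913249
Cytosolic non-specific dipeptidase	2.007756
1,4-alpha-glucan-branching enzyme	1.661596
Peroxidasin homolog	2.652092
Apolipoprotein B-100	2.316264
Receptor of activated protein C kinase 1	1.710004
Twisted gastrulation protein homolog 1	2.01397
Semaphorin-7A	1.562129
Clathrin heavy chain 1	1.994896
Gamma-glutamyl hydrolase	3.373673
Integrin beta-1	1.555267
Complement factor B	2.400909
Pigment epithelium-derived factor	1.849335
Prothrombin	2.055622
Fatty acid synthase	4.180675
Afamin	1.51762
Nucleobindin-1	1.886488
Gamma-enolase	2.397546
Malate dehydrogenase	2.673931
Keratin, type II cytoskeletal 2 epidermal	3.685358
Hemopexin	2.168184
Secernin-1	-2.2124
Xaa-Pro dipeptidase	-2.79808
Inter-alpha-trypsin inhibitor heavy chain H1	-3.22648
Protein FAM3C	-2.36545
Adenosylhomocysteinase	-1.99903
Neuropilin-2	-4.44478
Zyxin	-1.82006
Protein S100-A16	-2.95341
Vitamin K-dependent protein S	-1.85672
F-actin-capping protein subunit beta	-1.7749
Proliferating cell nuclear antigen	-1.88796
T-complex protein 1 subunit zeta	-4.29404
Target of Nesh-SH3	-2.26462
Nucleolin	-1.67984
Transforming growth factor-beta	-1.5896
Keratin, type I cytoskeletal 18	-1.65088
Heat shock protein HSP 90-alpha	-3.27354
Plectin	-2.76699
Glypican-1	-1.74094
Endoplasmin	-2.35994
Serglycin	-2.17844
Stathmin	-2.99955
Complement C1r subcomponent	-1.80893
Vinculin	-2.08319
Tubulin beta chain	-2.8778
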