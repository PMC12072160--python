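protein	log2fc
Alpha-N-acetylglucosaminidase	2.462605
Microfibril-associated glycoprotein	1.752348
Laminin subunit beta-2	2.343508
Gamma-glutamyl hydrolase	1.645163
Apolipoprotein B-100	1.798968
CD81 antigen	2.606067
Platelet-derived growth factor D	1.694437
Laminin subunit alpha-1	1.65653
Laminin subunit alpha-5	2.022212
Plasma serine protease inhibitor	2.619948
Golgi membrane protein 1	1.563853
Matrilin-2	2.426078
Twisted gastrulation protein homolog 1	2.406238
Nidogen-1	1.552728
Pigment epithelium-derived factor	1.784398
Prothrombin	1.824181
Pleiotrophin	1.998121
Growth arrest-specific protein 6	1.537331
Hemicentin-1	2.489509
Insulin-like growth factor-binding protein 4	2.567545
Collagen alpha-1(V) chain	1.952312
EGF-containing fibulin-like extracellular matrix protein 2	2.031291
CD109 antigen	1.808948
CD59 glycoprotein	2.017599
Complement C1s subcomponent	1.713896
Lysyl oxidase homolog 1	3.488902
Isoform 6 of Agrin	1.802008
Collagen alpha-1(XII) chain	1.88032
Complement factor H	1.787403
Fibulin-2	1.951293
Collagen alpha-2(V) chain	1.871816
Collagen alpha-1(IV) chain	1.548432
Collagen alpha-1(III) chain	1.932117
Basement membrane-specific heparan sulfate proteoglycan core protein	2.011173
Endoplasmin	-5.50561
Glucose-6-phosphate isomerase	-4.37476
Talin-1	-3.23422
Phosphoglucomutase-1	-2.7957
Rab GDP dissociation inhibitor beta	-3.28275
Elongation factor 1-alpha 1	-5.27955
Filamin-C	-4.19864
Protein S100-A11	-2.31899
Thioredoxin reductase 1	-2.32629
14-3-3 protein theta	-3.1384
Filamin-B	-2.98276
Ribonuclease inhibitor	-1.56277
60S ribosomal protein L10a	-1.85338
Plastin-3	-2.00479
L-lactate dehydrogenase B chain	-2.98947
Neuropilin-2	-2.08653
Protein disulfide-isomerase	-2.60304
Vinculin	-4.62631
Calreticulin	-3.09309
Coactosin-like protein	-1.90195
Heterogeneous nuclear ribonucleoproteins A2/B1	-1.88261
Phosphoglycerate mutase 1	-2.14715
Moesin	-4.018
Transgelin-2	-2.65851
Ubiquitin carboxyl-terminal hydrolase isozyme L1	-2.37848
Elongation factor 2	-1.73877
Di-N-acetylchitobiase	-1.51905
Endoplasmic reticulum chaperone BiP	-1.8288
Phosphoglycerate kinase 1	-1.51655
Filamin-A	-2.03801
Heat shock cognate 71 kDa protein	-3.03771
Alpha-actinin-1	-3.49252
Peroxiredoxin-1	-1.5572
Pyruvate kinase PKM	-2.16268
Profilin-1	-1.90567
Peptidyl-prolyl cis-trans isomerase A	-1.76446
Cofilin-1	-2.10461
14-3-3 protein zeta/delta	-1.60232
14-3-3 protein epsilon	-2.30693
Fructose-bisphosphate aldolase A	-2.28949
Alpha-enolase	-3.05139
Galectin-1	-2.43163
Vimentin	-2.50007
Keratin, type II cytoskeletal 1	-2.22575
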