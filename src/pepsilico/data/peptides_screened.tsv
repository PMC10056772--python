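# Screened bioactive-peptide fixture: 22 peptides with external bioactivity
# scores (threshold 0.5 already applied) and their reported average MWs (Da).
id	sequence	parent_protein	score	reported_mw
p01	KNAMPAFNGRL	Cytochrome C6	0.86	1218.4
p02	RALGFDFRR	Chlorophyll a/b binding light-harvesting protein	0.83	1137.3
p03	KAPGFGDRR	60 kDa chaperonin	0.78	1003.1
p04	RHTPFFKG	Elongation factor	0.77	989.1
p05	RNPAIFRG	Carbohydrate-selective porin OprB	0.75	930.1
p06	KFFYPNFQTRV	Phycobilisome linker polypeptide	0.75	1446.7
p07	RGQWTVGFNRM	Phycobilisome linker polypeptide	0.71	1351.6
p08	KFFYGNSQVRF	Phycobilisome linker polypeptide	0.68	1392.6
p09	KAGYLFPEIARR	LL-diaminopimelate aminotransferase	0.67	1420.7
p10	RDNVLRF	Orange carotenoid protein	0.63	919.0
p11	RIPPYRN	Polypeptide-transport-associated domain protein ShlB-type	0.63	915.1
p12	RNLGAGSQFNLPRN	Extracellular solute-binding protein family 3	0.62	1543.7
p13	RSIPTLMIFKG	Thioredoxin	0.60	1262.6
p14	RQMSLLLRR	Hypothetical protein	0.60	1172.4
p15	RLQLLARF	Methyltransferase type 11	0.58	1016.2
p16	RFGIISVRF	Uncharacterized protein	0.58	1094.3
p17	KFVVGGPQGDSGLTGRK	S-adenosylmethionine synthase	0.58	1702.9
p18	KVAINGFGRI	Glyceraldehyde-3-phosphate dehydrogenase	0.57	1074.3
p19	KADSLISGAAQAVYNKF	C-phycocyanin alpha subunit	0.54	1783.0
p20	KIGLFGGAGVGKT	ATP synthase subunit beta	0.54	1204.4
p21	RAGGYTRL	Dihydroorotase	0.52	893.0
p22	KRPDFIAPGGNAAGQRE	Phycobilisome protein	0.52	1783.9
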