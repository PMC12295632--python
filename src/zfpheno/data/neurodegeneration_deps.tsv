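gene_symbol	protein_name	log2fc	direction	significant
ACADVL	Very long-chain specific acyl-CoA dehydrogenase, mitochondrial	1.562	↑	true
ACAT1	Acetyl-CoA acetyltransferase, mitochondrial	4.168	↑	true
ALCAMA	CD166 antigen homolog A	2.412	↑	true
ATP2A2A	Calcium-transporting ATPase	-2.398	↓	true
ATP2B1A	Calcium-transporting ATPase	-2.477	↓	true
ATP2B4	ATPase, Ca++ transporting, plasma membrane 4	-1.882	↓	true
ATP5MJ	6.8 kDa mitochondrial proteolipid-like	2.322	↑	true
ATP5PD	ATP synthase subunit d, mitochondrial	1.499	↑	true
CAMK2B1	calcium/calmodulin-dependent protein kinase	-1.503	↓	true
CAPN2L	Calpain-2 catalytic subunit	-5.777	↓	true
CKMT2B	Creatine kinase S-type, mitochondrial	1.477	↑	true
CS	Citrate synthase, mitochondrial	-1.614	↓	true
DLST	Dihydrolipoyllysine-residue succinyltransferase component of 2-oxoglutarate dehydrogenase complex, mitochondrial	-1.652	↓	true
DMGDH	Dimethylglycine dehydrogenase, mitochondrial	-3.745	↓	true
DNAH2	Dynein axonemal heavy chain 2 isoform X1	2.464	↑	true
FDX1	Adrenodoxin, mitochondrial	1.468	↑	true
ICN2	Protein S100	-1.669	↓	true
INAB	Internexin neuronal intermediate filament protein, alpha b	-1.694	↓	true
LONP1	Lon protease homolog, mitochondrial	1.827	↑	true
NDUFS6	NADH dehydrogenase [ubiquinone] iron-sulfur protein 6, mitochondrial	1.77	↑	true
NEFMB	Neurofilament medium chain b	-2.489	↓	true
PARK7	Parkinson disease protein 7 homolog	1.946	↑	true
PRDX3	Thioredoxin-dependent peroxide reductase, mitochondrial	-1.548	↓	true
PSMA8	Proteasome subunit alpha type	2.005	↑	true
PSMB10	Proteasome subunit beta	3.793	↑	true
PSMB3	Proteasome subunit beta	2.26	↑	true
PSMB5	Proteasome subunit beta	3.372	↑	true
PSMC1B	Proteasome	2.198	↑	true
PSMC5	26S proteasome regulatory subunit 8	-3.234	↓	true
PSMD11B	26S proteasome non-ATPase regulatory subunit 11B	1.633	↑	true
SDHA	Succinate dehydrogenase [ubiquinone] flavoprotein subunit, mitochondrial	-2.272	↓	true
SI:CH211-125O16.4	Neuroblast differentiation-associated protein AHNAK	-1.567	↓	true
SLC25A11	Mitochondrial 2-oxoglutarate/malate carrier protein	-2.773	↓	true
SLC25A3B	Solute carrier family 25 member 3	-2.134	↓	true
STIP1	Stress-induced-phosphoprotein 1	-1.573	↓	true
TOMM7	Mitochondrial import receptor subunit TOM7 homolog	1.909	↑	true
UQCRC1	Cytochrome b-c1 complex subunit 1, mitochondrial	2.115	↑	true
UQCRFS1	Cytochrome b-c1 complex subunit Rieske, mitochondrial	-1.516	↓	true
VAMP2	Vesicle-associated membrane protein 2	-4.728	↓	true
VAPB	Vesicle-associated membrane protein-associated protein B/C isoform X1	3.207	↑	true
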