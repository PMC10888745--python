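perturbagen_id	drug_id	drug_name	mean_zhang_score	target_gene_symbol	target_uniprot_id	target_protein_name	action
BRD-K33106058_DB00987	DB00987	cytarabine	0.402339	POLB	P06746	DNA polymerase beta	inhibitor
BRD-K89626439_DB00877	DB00877	sirolimus	0.396491	MTOR	P42345	Serine/threonine-protein kinase mTOR	inhibitor
BRD-K72238567_DB01073	DB01073	fludarabine	0.20117	POLA1	P09884	DNA polymerase alpha catalytic subunit	inhibitor
BRD-K72238567_DB01073	DB01073	fludarabine	0.20117	RRM1	P23921	Ribonucleoside-diphosphate reductase large subunit	inhibitor
BRD-A38030642_DB00091	DB00091	cyclosporine	0.192982	PPP3R2	Q96LZ3	Calcineurin subunit B type 2	inhibitor
BRD-A38030642_DB00091	DB00091	cyclosporine	0.192982	PPIA	P62937	Peptidyl-prolyl cis-trans isomerase A	inhibitor
BRD-A16311756_DB00392	DB00392	profenamine	0.166082	CHRM1	P11229	Muscarinic acetylcholine receptor M1	antagonist
BRD-A16311756_DB00392	DB00392	profenamine	0.166082	CHRM2	P08172	Muscarinic acetylcholine receptor M2	antagonist
BRD-A16311756_DB00392	DB00392	profenamine	0.166082	GRIN3A	Q8TCU5	Glutamate receptor ionotropic, NMDA 3A	antagonist
BRD-K89732114_DB00831	DB00831	trifluoperazine	0.153216	DRD2	P14416	Dopamine D2 receptor	antagonist
BRD-K89732114_DB00831	DB00831	trifluoperazine	0.153216	CALY	Q9NYX4	Neuron-specific vesicular protein calcyon	antagonist
BRD-K89732114_DB00831	DB00831	trifluoperazine	0.153216	ADRA1A	P35348	Alpha-1A adrenergic receptor	antagonist
BRD-K89732114_DB00831	DB00831	trifluoperazine	0.153216	CALM	P0DP23	Calmodulin	inhibitor
BRD-K89732114_DB00831	DB00831	trifluoperazine	0.153216	S100A4	P26447	Protein S100-A4	inhibitor
BRD-K43389675_DB00694	DB00694	daunorubicin	0.145029	TOP2A	P11388	DNA topoisomerase 2-alpha	inhibitor
BRD-K43389675_DB00694	DB00694	daunorubicin	0.145029	TOP2B	Q02880	DNA topoisomerase 2-beta	inhibitor
BRD-K23478508_DB00390	DB00390	digoxin	0.138012	ATP1A1	P05023	Sodium/potassium-transporting ATPase subunit alpha-1	inhibitor
BRD-A59985574_DB01030	DB01030	topotecan	0.127485	TOP1	P11387	DNA topoisomerase 1	inhibitor
BRD-A59985574_DB01030	DB01030	topotecan	0.127485	TOP1MT	Q969P6	DNA topoisomerase I, mitochondrial	inhibitor
BRD-K04548931_DB00997	DB00997	doxorubicin	0.100585	TOP1	P11387	DNA topoisomerase 1	inhibitor
BRD-K04548931_DB00997	DB00997	doxorubicin	0.100585	TOP2A	P11388	DNA topoisomerase 2-alpha	inhibitor
BRD-K04548931_DB00997	DB00997	doxorubicin	0.100585	TOP2B	Q02880	DNA topoisomerase 2-beta	inhibitor
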