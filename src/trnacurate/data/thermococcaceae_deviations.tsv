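# Literature-curated deviations of the 20 Thermococcaceae tRNA gene sets in
# GtRNAdb (Data Release 19, June 2021) from the standard archaeal 46-type set.
# direction: + = additional listed gene, - = apparently missing standard type.
# Missing-type rows carry no coordinates or scores.
# isotype_score: score listed by GtRNAdb; local_score: score from a local
# tRNAscan-SE 2.0.6 rerun with pseudogene detection active, where reported.
# trnascan_class/gtrnadb_class: Ps = predicted pseudogene, St = standard
# 20-AA tRNA, Und = undetermined isotype.
# category: 1a = CRISPR-derived fragment, 1b = integration-derived fragment
# (attR), 2 = isotype misassignment from ambiguous (N) sequence,
# 3 = legitimate additional gene.  pair_id links the additional/missing
# halves of a misassignment.
anomaly_id	genome_id	organism	direction	isotype	anticodon	size_bp	isotype_score	local_score	seq_id	start	end	strand	trnascan_class	gtrnadb_class	category	pair_id
1	T_gammatolerans_EJ3	Thermococcus gammatolerans EJ3	+	Ser	CGA	53	10.4		chromosome	621672	621724	-	Ps	St	1b
2	T_nautili_30-1	Thermococcus nautili 30-1	+	Leu	CAA	218	2.3		NZ_CP007264.1	706451	706668	+	Ps	St	1a
3	T_kodakarensis_KOD1	Thermococcus kodakarensis KOD1	+	Arg	TCT	83	21.4		chromosome	320075	320157	-	Ps	St	1b
4	T_kodakarensis_KOD1	Thermococcus kodakarensis KOD1	+	Val	CAC	72	83.4		chromosome	62858	62929	-	St	St	1b
5	P_yayanosii_CH1	Pyrococcus yayanosii CH1	+	Gln	TTG	90	13.4		NC_015680.1	1321660	1321749	-	Ps	St	1b
6	T_sp_ES1	Thermococcus sp. ES1	+	Ser	CGA	69	30.9		chromosome	747982	748050	+	Ps	St	1b
7	T_sp_ES1	Thermococcus sp. ES1	+	Und	NNN	127	16.8		chromosome	603860	603986	-	Und	Und	1b
8	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	+	Leu	CAA	76	6.3		NC_022084.1	326949	327024	+	Ps	St	1b
9	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	+	Leu	NAG	88	135.1	134.9	NC_022084.1	648439	648526	+	Ps	St	2	10
10	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	-	Leu	CAG							Ps	St	2	9
11	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	+	Pro	NGG	78	120.3	120.3	NC_022084.1	546230	546307	-	Ps	St	2	12
12	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	-	Pro	GGG							Ps	St	2	11
13	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	+	Und	NTG	76	117.9	117.9	NC_022084.1	825204	825279	-	Ps	St	2	14
14	T_litoralis_DSM5473	Thermococcus litoralis DSM 5473	-	Gln	CTG							Ps	St	2	13
15	Pa_pacificus_DY20341	Palaeococcus pacificus DY20341	+	Ala	TGC	77	122.6		NZ_CP006019.1	1527238	1527314	-	St	St	3
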