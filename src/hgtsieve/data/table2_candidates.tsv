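gene_id	type_group	annotation	protein_length	length_flagged	gc	intron_count	est_count	cloned	microarray	probe_id	chromosome	scaffold	start	end	strand	top_hit_species	top_hit_score	top_hit_evalue	top_hit_identity_pct
BGIBMGA000070	T000070	yolk protein 1	267	0	0.36	0	0	0	1	sw05607	24	nscaf1108	2533757	2534560	-	Methanosarcina barkeri fusaro	446	1e-45	37.6
BGIBMGA001284	T001284	unknown	242	0	0.45	0	1	0	1	sw09798	13	nscaf1898	13442553	13443281	+	Lactococcus lactis cremoris MG1363	492	3e-51	41.3
BGIBMGA002521	T002521	gamma-glutamyltranspeptidase	526	0	0.43	0	0	0	1	sw02154	9	nscaf2511	3929359	3930939	+	Serratia proteamaculans 568	1642	0	59
BGIBMGA005555	T005555	beta-fructofuranosidase (BmSuc2)	506	0	0.49	0	0	1	1	sw13105	17	nscaf2829	2704806	2706326	-	Bacillus amyloliquefaciens FZB42	876	4e-95	39
BGIBMGA005696	T005555	beta-fructofuranosidase (BmSuc1)	488	0	0.49	0	23	1	1	sw02518		nscaf2830	395557	397023	-	Bacillus licheniformis ATCC 14580	967	1e-105	45.6
BGIBMGA005615	T005615	zinc-type alcohol dehydrogenase-like protein	336	1	0.42	0	3	0	1	sw13511	17	nscaf2829	935343	936353	+	Alicyclobacillus acidocaldarius DSM 446	478	2e-49	52.1
BGIBMGA007146	T007146	kynureninase (BmKynu)	426	0	0.42	0	1	1	1	sw14459	21	nscaf2868	1232908	1234188	-	Alkaliphilus oremlandii OhILAs	1237	1e-137	54.5
BGIBMGA007766	T007766	glycerophosphoryl diester phosphodiesterase	378	0	0.45	0	1	0	1	sw04248	15	nscaf2888	43197	44333	+	Pseudomonas aeruginosa	1252	1e-138	67.6
BGIBMGA007767	T007766	glycerophosphoryl diester phosphodiesterase	372	1	0.44	0	9	0	1	sw16854	15	nscaf2888	49514	50632	+	Pseudomonas aeruginosa	1145	1e-126	67.1
BGIBMGA008215	T008215	N-methyltryptophan oxidase	369	0	0.49	0	2	0	1	sw06048	18	nscaf2899	584306	585415	-	Serratia proteamaculans 568	919	1e-100	48.6
BGIBMGA008709	T008709	chitinase (BmChi-h)	551	0	0.52	0	25	1	1	sw08485	7	nscaf2912	405540	407195	+	Serratia proteamaculans 568	2100	0	72.9
BGIBMGA009498	T009498	ankyrin repeat domain protein	1632	0	0.38	0	0	0	1	sw09000	14	nscaf2953	1379654	1384552	+	Wolbachia endosymbiont of Culex quinquefasciatus Pel	1312	1e-145	33.2
BGIBMGA010285	T010285	NAD-dependent epimerase/dehydratase	318	0	0.48	0	2	0	1	sw10878	7	nscaf2986	5498917	5499873	+	Photorhabdus asymbiotica	906	9e-99	53.8
BGIBMGA010866	T010285	NAD-dependent epimerase/dehydratase	322	0	0.45	0	2	0	1	sw09038	22	nscaf3005	1015921	1016889	-	Photorhabdus asymbiotica	935	1e-102	57.9
BGIBMGA011199	T011199	glucose-1-phosphatase	391	1	0.40	0	1	0	1	sw22572	23	nscaf3026	4939042	4940021	-	Serratia proteamaculans 568	701	6e-75	40.8
BGIBMGA011200	T011199	glucose-1-phosphatase	187	0	0.39	0	0	0	0		23	nscaf3026	4936929	4937492	-
BGIBMGA011201	T011199	glucose-1-phosphatase	391	1	0.39	0	0	0	1	sw22571	23	nscaf3026	4933133	4934308	-	Serratia proteamaculans 568	678	3e-72	40.2
BGIBMGA011202	T011199	glucose-1-phosphatase	391	1	0.38	0	0	0	1	sw22728	23	nscaf3026	4926408	4927358	-	Serratia proteamaculans 568	676	5e-72	39
BGIBMGA011203	T011199	glucose-1-phosphatase	391	1	0.38	0	1	0	1	sw22676	23	nscaf3026	4907767	4908942	-	Serratia proteamaculans 568	673	1e-71	39.6
BGIBMGA011204	T011199	glucose-1-phosphatase	394	1	0.38	0	1	0	1	sw06503	23	nscaf3026	4903958	4905142	-	Serratia proteamaculans 568	783	2e-84	42.2
BGIBMGA012123	T012123	pyridoxal-5'-phosphate-dependent protein beta subunit	325	0	0.48	0	0	0	1	sw06559	11	nscaf3034	3775486	3776463	+	Methylobacterium radiotolerans JCM 2831	738	4e-79	47.2
BGIBMGA013995	T013995	glycosyl hydrolase	1077	0	0.40	0	0	0	1	sw05614;sw12345	28	nscaf3099	3081904	3085134	+	Enterococcus faecalis V583	3149	0	52.8
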