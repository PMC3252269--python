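type_group	gene_ids	top_blast_hit	tree_evidence	donor_genus	relationship	phylum	class	order	family
T002521	BGIBMGA002521	Serratia proteamaculans 568	a set of bacteria	Serratia	insect pathogen	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae
T005555	BGIBMGA005555;BGIBMGA005696	Bacillus amyloliquefaciens FZB42;Bacillus licheniformis ATCC 14580	a set of bacteria	Bacillus	insect pathogen	Firmicutes	Bacilli	Bacillales	Bacillaceae
T005615	BGIBMGA005615	Alicyclobacillus acidocaldarius DSM 446	Listeria grayi DSM 20601	Listeria	-	Firmicutes	Bacilli	Bacillales	Listeriaceae
T007146	BGIBMGA007146	Alkaliphilus oremlandii OhILAs	Listeria grayi	Listeria	-	Firmicutes	Bacilli	Bacillales	Listeriaceae
T007766	BGIBMGA007766;BGIBMGA007767	Pseudomonas aeruginosa	Pseudomonas aeruginosa UCBPP-PA14	Pseudomonas	insect pathogen	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Pseudomonadaceae
T008215	BGIBMGA008215	Serratia proteamaculans 568	a set of bacteria	Serratia	insect pathogen	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae
T008709	BGIBMGA008709	Serratia proteamaculans 568	a set of bacteria	Serratia	insect pathogen	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae
T009498	BGIBMGA009498	Wolbachia endosymbiont of Culex quinquefasciatus Pel	-	Wolbachia	insect symbiont	Proteobacteria	Alphaproteobacteria	Rickettsiales	Rickettsiaceae
T010285	BGIBMGA010285;BGIBMGA010866	Photorhabdus asymbiotica	Photorhabdus asymbiotica	Photorhabdus	insect pathogen	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae
T010285	BGIBMGA010285;BGIBMGA010866	Photorhabdus asymbiotica	Photorhabdus luminescens	Photorhabdus	insect pathogen	Proteobacteria	Gammaproteobacteria	Enterobacteriales	Enterobacteriaceae
T011199	BGIBMGA011199;BGIBMGA011200;BGIBMGA011201;BGIBMGA011202;BGIBMGA011203;BGIBMGA011204	Serratia proteamaculans 568	Aggregatibacter aphrophilus nj8700	Serratia	insect pathogen	Proteobacteria	Gammaproteobacteria	Pasteurellales	Pasteurellaceae
T012123	BGIBMGA012123	Methylobacterium radiotolerans JCM 2831	Methylobacterium radiotolerans JCM 2831	Methylobacterium	plant symbiont	Proteobacteria	Alphaproteobacteria	Rhizobiales	Methylobacteriaceae
T012123	BGIBMGA012123	Methylobacterium radiotolerans JCM 2831	Sagittula stellata E-37	Methylobacterium	plant symbiont	Proteobacteria	Alphaproteobacteria	Rhizobiales	Methylobacteriaceae
T013995	BGIBMGA013995	Enterococcus faecalis V583	Enterococcus faecalis	Enterococcus	insect pathogen	Firmicutes	Bacilli	Lactobacillales	Enterococcaceae
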