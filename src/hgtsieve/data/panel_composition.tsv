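taxon	rank	organisms	species
total	total	994	680
eubacteria	domain	926	621
archaebacteria	domain	68	59
Proteobacteria	phylum	486	315
Firmicutes	phylum	184	99
Gammaproteobacteria	class	236	125
Bacilli	class	133	63
Serratia	genus		1
Photorhabdus	genus		2
Pseudomonas	genus		9
Bacillus	genus		11
entomopathogenic_genera	genus_group		23
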