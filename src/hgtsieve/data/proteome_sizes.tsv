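species	proteome_size	after_blast1	after_blast2	after_phylogenetics
Drosophila melanogaster	20590	2251	179	0
Anopheles gambiae	12659	1337	154	0
Bombyx mori	14623	1176	163	22
Tribolium castaneum	9833	1493	154	0
Apis mellifera	9257	1222	183	79
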