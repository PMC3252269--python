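set_label	n_species
protist	29
fungus	48
plant	13
insect	22
non_insect_arthropod	8
non_arthropod_metazoan	22
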