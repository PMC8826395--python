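# Published homolog-survey count pairs: unique species with a hit vs species
# with proteomes in the searched database, per taxonomic group.
group	taxid	n_hit_species	n_total_species	dp
Bacteria	2	295	38842	2
Cyanobacteria	1117	56	506	2
Actinobacteria	201174	136	4870	2
Proteobacteria	1223	69	16196	2
Eukaryotes	2759	406	2241	2
Animals (Metazoa)	33208	229	612	2
Insects	50557	0	142	2
Worms (Annelida)	6340	0	2	2
Fungi	4751	177	1098	2
Yeast (Ascomycota)	4890	176	760	2
Yeast (Saccharomyces)	4930	0	13	2
Plants (Viridiplantae)	33090	0	244	2
Opisthokonta	33208 and 4751	406	1710	2
Pre-opisthokonta	2759 NOT (33208|4751)	0	531	2
Archaea	2157	1	2107	2
Viruses	10239	1	99210	3
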