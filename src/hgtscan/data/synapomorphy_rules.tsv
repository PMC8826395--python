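# Default residue rules for typing PADI-like sequences, in 1-based ungapped
# human-PADI2 coordinates.  kind: 'conserved' rules must match for any
# confident call; 'diagnostic' rules discriminate the three-domain
# cyanobacterial/animal type (Ai) from the two-domain actinobacterial/fungal
# type (Bi).  States are per-position, comma-separated, with '/' separating
# tolerated alternatives; '-' means no states defined (advisory rules report
# observed residues only).  positions accepts single sites, comma lists and
# 'start-end' ranges.  severity: critical rules drive the call, advisory rules
# are reported but do not affect it (pending user curation).
name	kind	severity	positions	ai_states	bi_states	note
catalytic_site	conserved	critical	351,471,473,647	D,H,D,C	-	catalytic/substrate residues conserved in all PADIs
ca_site6	conserved	critical	125,131	D/N,E/D	-	calcium site 6; D125N and E131D are binding-preserving substitutions
ca_switch_389	diagnostic	critical	389	D	G	calcium switch: aspartate coordinates ordered Ca binding; glycine is incompetent
triple_his_300_302	diagnostic	critical	300,301,302	-	H,H,H	distinctive triple-histidine motif in the PAD_M/PAD_C connector beta-sheet
ca_sites_2_4	diagnostic	advisory	152,154,157	-	-	calcium sites 2 and 4 motifs appear exclusive to the Ai type; not enumerated
bi_region_155_180	diagnostic	advisory	155-180	-	-	region within calcium sites 3-5 conserved to a different motif in the Bi type
connector_292_302	diagnostic	advisory	292-302	-	-	ten-residue connector beta-sheet; conserved differently in the two types
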