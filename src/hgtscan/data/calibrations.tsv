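# Fossil-record node-age calibrations (normal priors), deepest first.
# taxon_set: pipe-separated tip labels of the calibrated (monophyletic) clade.
# Taxa: HS Homo sapiens, MM Mus musculus, AM Alligator mississippiensis,
# CMy Chelonia mydas, GG Gallus gallus, XL Xenopus laevis, OM Oncorhynchus
# mykiss, CMi Callorhinchus milii, BF Branchiostoma floridae, PC Priapulus
# caudatus.
taxon_set	mean_Ma	sigma_Ma
HS|MM|AM|CMy|GG|XL|OM|CMi|BF|PC	797.0	72.5
HS|MM|AM|CMy|GG|XL|OM|CMi|BF	692.5	57.5
HS|MM|AM|CMy|GG|XL|OM|CMi	473.5	14.0
HS|MM|AM|CMy|GG|XL|OM	435.0	6.5
HS|MM|AM|CMy|GG	311.0	7.5
HS|MM	89.5	3.0
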