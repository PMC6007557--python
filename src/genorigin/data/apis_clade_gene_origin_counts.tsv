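# Published per-species gene-origin counts for sequenced Apis-clade
# Spiroplasma genomes (four-way best-hit classification; see docs/methods.md).
# reference_only=1 marks the divergent species for which the best-hit
# classification is not applicable and which is excluded from averages.
species	native	species_specific	hgt_low	hgt_high	reference_only
Spiroplasma clarkii	641	472	142	91	0
Spiroplasma helicoides	679	198	99	21	0
Spiroplasma culicicola	709	228	98	36	0
Spiroplasma apis	728	281	109	33	0
Spiroplasma turonicum	780	149	115	20	0
Spiroplasma corruscae	667	218	70	18	0
Spiroplasma litorale	789	151	105	21	0
Spiroplasma cantharicola	745	123	104	45	0
Spiroplasma diminutum	770	119	115	4	0
Spiroplasma taiwanense	728	50	67	13	0
Spiroplasma sabaudiense	243	338	178	165	1
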