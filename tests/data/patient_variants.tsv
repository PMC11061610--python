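chrom	pos	ref	alt	ref_depth	alt_depth	f1r2_alt	f2r1_alt	consequence_level
chr1	10011	A	T	15	4	2	2	MODERATE
chr2	20022	C	G	40	3	1	2	HIGH
chr3	30033	G	A	50	5	2	1	MODERATE
chr4	40044	T	C	90	8	4	4	HIGH
chr5	50055	A	G	60	6	3	3	MODERATE
chr6	60066	C	T	30	10	5	4	LOW
chr7	70077	G	C	25	12	6	5	MODIFIER
chr8	80088	T	A	16	4	2	2	MODERATE
chr9	90099	A	C	36	4	2	2	HIGH
chr10	100100	C	A	100	50	20	20	HIGH
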