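study	class	transitions	transversions	one_bp_deletions	one_bp_insertions	other
CDEII	centromere	46	68	4	0	18
Genome-wide (WT)	wild-type	12	19	1	0	1
URA3 Lang (WT)	wild-type	46	121	22	3	15
CAN1 Lang (WT)	wild-type	65	85	56	8	13
URA3 Hicks (WT)	wild-type	19	27	5	1	9
URA3 Hicks (GC)	gene-conversion	32	24	32	1	14
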