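gene_id	cds_id	votes_L1	survived_L1	votes_L2	survived_L2	votes_L3	survived_L3	survived_all	total_votes
NUL0004	NUL0004.c1	0	False	0	False	0	False	False	0
NUL0004	NUL0004.c2	0	False	0	False	0	False	False	0
POS0004	POS0004.c1	3	True	3	True	3	True	True	9
POS0000	POS0000.c1	3	True	3	True	3	True	True	9
NUL0005	NUL0005.c1	0	False	0	False	0	False	False	0
POS0005	POS0005.c1	3	True	3	True	3	True	True	9
POS0002	POS0002.c1	3	True	3	True	3	True	True	9
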