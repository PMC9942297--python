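gene_id	cds_id	protein_id	chromosome
NUL0000	NUL0000.c1	NUL0000.p1	chr1
NUL0001	NUL0001.c1	NUL0001.p1	chr2
NUL0001	NUL0001.c2	NUL0001.p2	chr2
NUL0002	NUL0002.c1	NUL0002.p1	chr3
NUL0003	NUL0003.c1	NUL0003.p1	chr1
NUL0004	NUL0004.c1	NUL0004.p1	chr2
NUL0004	NUL0004.c2	NUL0004.p2	chr2
NUL0005	NUL0005.c1	NUL0005.p1	chr3
POS0000	POS0000.c1	POS0000.p1	chr1
POS0000	POS0000.c2	POS0000.p2	chr1
POS0001	POS0001.c1	POS0001.p1	chr2
POS0002	POS0002.c1	POS0002.p1	chr3
POS0003	POS0003.c1	POS0003.p1	chr1
POS0003	POS0003.c2	POS0003.p2	chr1
POS0004	POS0004.c1	POS0004.p1	chr2
POS0004	POS0004.c2	POS0004.p2	chr2
POS0005	POS0005.c1	POS0005.p1	chr3
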