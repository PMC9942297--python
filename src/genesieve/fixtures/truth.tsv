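gene_id	chromosome	true_class
POS0000	chr1	positive
POS0001	chr2	positive
POS0002	chr3	positive
POS0003	chr1	positive
POS0004	chr2	positive
POS0005	chr3	positive
NUL0000	chr1	null
NUL0001	chr2	null
NUL0002	chr3	null
NUL0003	chr1	null
NUL0004	chr2	null
NUL0005	chr3	null
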