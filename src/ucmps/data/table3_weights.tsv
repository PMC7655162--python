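gene_id	gene_weight
DUOXA2	3.1869
S100A8	3.0181
TNFRSF6B	3.7603
MMP1	4.5608
CSF3R	3.0028
FER1L4	3.0258
COL7A1	3.6774
FPR1	3.0121
FAM65C	3.0217
AQP9	3.0115
MIAT	3.0328
PROK2	3.0119
RP6	4.5567
CSF3	4.0558
ADGRG3	3.0259
HCAR2	3.1662
CXCR1	3.0118
ADAMTS14	4.3368
PTGIR	3.0149
DUOXA1	3.2243
CD300E	4.3764
LILRA1	3.1524
HCG4P11	1.1187
LINC00528	3.7521
PERM1	4.2631
RUFY4	4.7713
POM121L9P	4.6224
LCNL1	4.5594
CLEC6A	3.0244
RIMS4	4.7128
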