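phenotype	WT	TET2	JAK2	TET2_first	JAK2_first
SC_self_renewal	1	2	1	2	2
CMP_expansion	1	2	1	2	1
GMP_expansion	1	2	2	2	2
GMP_differentiation	1	0	1	1	1
Erythroid_differentiation	1	0	2	1	2
MEP_expansion	1	1	2	2	2
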