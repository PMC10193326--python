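# SYNTHETIC RECONSTRUCTION. The CLARITY week-96 deconvolution-to-flow mapping was
# published only as counts (26 of 66 signatures matched: 9 CIBERSORT + 17 xCell,
# against 9 flow phenotypes) plus worked examples (CD3+ counts mapped to
# specialised T-cell signatures incl. resting/activated memory CD4, Tregs, Tgd,
# Th1, naive CD8). This table encodes a mapping consistent with those counts and
# examples; it is not the authors' exact table.
signature_id	flow_phenotype
cibersort.NK.cells.resting	NK.CD16.CD56
cibersort.NK.cells.activated	NK.CD16.CD56
cibersort.B.cells.naive	B.CD19
cibersort.B.cells.memory	B.CD19
cibersort.T.cells.CD8	T.CD8
cibersort.T.cells.CD4.naive	NAIVE.T.CD4.CD45RA
cibersort.T.cells.CD4.memory.resting	MEMORY.T.CD4.CD45RO
cibersort.T.cells.CD4.memory.activated	T.CD3
cibersort.T.cells.regulatory.Tregs	T.CD3
xcell.B.cells	B.CD19
xcell.Naive.B.cells	B.CD19
xcell.Memory.B.cells	B.CD19
xcell.Class.switched.memory.B.cells	B.CD19
xcell.CD4.T.cells	T.CD4
xcell.CD4.naive.T.cells	NAIVE.T.CD4.CD45RA
xcell.CD4.memory.T.cells	MEMORY.T.CD4.CD45RO
xcell.CD4.Tcm	MEMORY.T.CD4.CD45RO
xcell.CD4.Tem	MEMORY.T.CD4.CD45RO
xcell.CD8.T.cells	T.CD8
xcell.CD8.naive.T.cells	NAIVE.T.CD8.CD45RA
xcell.CD8.Tcm	MEMORY.T.CD8.CD45RO
xcell.CD8.Tem	MEMORY.T.CD8.CD45RO
xcell.NK.cells	NK.CD16.CD56
xcell.Th1.cells	T.CD3
xcell.Tgd.cells	T.CD3
xcell.Tregs	T.CD3
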