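cell_type	signature_id
B cells naive	cibersort.B.cells.naive
B cells memory	cibersort.B.cells.memory
Plasma cells	cibersort.Plasma.cells
T cells CD8	cibersort.T.cells.CD8
T cells CD4 naive	cibersort.T.cells.CD4.naive
T cells CD4 memory resting	cibersort.T.cells.CD4.memory.resting
T cells CD4 memory activated	cibersort.T.cells.CD4.memory.activated
T cells follicular helper	cibersort.T.cells.follicular.helper
T cells regulatory (Tregs)	cibersort.T.cells.regulatory.Tregs
T cells gamma delta	cibersort.T.cells.gamma.delta
NK cells resting	cibersort.NK.cells.resting
NK cells activated	cibersort.NK.cells.activated
Monocytes	cibersort.Monocytes
Macrophages M0	cibersort.Macrophages.M0
Macrophages M1	cibersort.Macrophages.M1
Macrophages M2	cibersort.Macrophages.M2
Dendritic cells resting	cibersort.Dendritic.cells.resting
Dendritic cells activated	cibersort.Dendritic.cells.activated
Mast cells resting	cibersort.Mast.cells.resting
Mast cells activated	cibersort.Mast.cells.activated
Eosinophils	cibersort.Eosinophils
Neutrophils	cibersort.Neutrophils
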