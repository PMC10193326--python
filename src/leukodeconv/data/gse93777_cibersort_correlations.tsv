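signature_id	flow_phenotype	spearman_r	p_value	fdr	assessment
cibersort.B.cells.memory	B.CELL.rWBC	0.519	<0.001	0.000	Strong correlation
cibersort.B.cells.naive	B.CELL.rWBC	0.164	0.011	0.017	Weak correlation
cibersort.Dendritic.cells.resting	DC.rWBC	0.188	0.003	0.006	Weak correlation
cibersort.Eosinophils	EOSINOPHIL.rWBC	0.146	0.024	0.031	Weak correlation
cibersort.Mast.cells.resting	BASOPHIL.rWBC	0.148	0.022	0.031	Weak correlation
cibersort.Monocytes	MONOCYTE.rWBC	0.604	<0.001	0.000	Strong correlation
cibersort.Neutrophils	NEUTROPHIL.rWBC	0.798	<0.001	0.000	Strong correlation
cibersort.NK.cells.resting	NK.rWBC	0.583	<0.001	0.000	Strong correlation
cibersort.Plasma.cells	PLASMABLAST.rWBC	0.610	<0.001	0.000	Strong correlation
cibersort.T.cells.CD4.memory.resting	MEMORY.CD4.rWBC	0.079	0.222	0.247	No correlation
cibersort.T.cells.CD4.naive	NAIVE.CD4.rWBC	0.691	<0.001	0.000	Strong correlation
cibersort.T.cells.CD8	CD8.T.rWBC	0.776	<0.001	0.000	Strong correlation
cibersort.T.cells.gamma.delta	GAMMA.DELTA.T.rWBC	-0.078	0.229	0.247	No correlation
cibersort.T.cells.regulatory.Tregs	TREG.rWBC	-0.021	0.744	0.744	No correlation
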