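signature_id	flow_phenotype	spearman_r	p_value	fdr	assessment
xcell.B.cells	B.CELL.rWBC	0.768	<0.001	0.000	Strong correlation
xcell.Basophils	BASOPHIL.rWBC	0.016	0.802	0.802	No or negative correlation
xcell.CD4.memory.T.cells	MEMORY.CD4.rWBC	0.434	<0.001	0.000	Moderate correlation
xcell.CD4.naive.T.cells	NAIVE.CD4.rWBC	0.786	<0.001	0.000	Strong correlation
xcell.CD4.T.cells	CD4.T.rWBC	0.789	<0.001	0.000	Strong correlation
xcell.CD4.Tcm	MEMORY.CD4.rWBC	0.466	<0.001	0.000	Moderate correlation
xcell.CD4.Tem	MEMORY.CD4.rWBC	0.523	<0.001	0.000	Strong correlation
xcell.CD8.naive.T.cells	NAIVE.CD8.rWBC	-0.141	0.029	0.035	No or negative correlation
xcell.CD8.T.cells	CD8.T.rWBC	0.850	<0.001	0.000	Strong correlation
xcell.CD8.Tcm	MEMORY.CD8.rWBC	0.488	<0.001	0.000	Moderate correlation
xcell.CD8.Tem	CD45RA.MEMORY.CD8.rWBC	0.450	<0.001	0.000	Moderate correlation
xcell.cDC	MDC.rWBC	0.289	<0.001	0.000	Weak correlation
xcell.Class.switched.memory.B.cells	B.CELL.rWBC	0.738	<0.001	0.000	Strong correlation
xcell.DC	DC.rWBC	0.062	0.340	0.370	No or negative correlation
xcell.Eosinophils	EOSINOPHIL.rWBC	0.479	<0.001	0.000	Moderate correlation
xcell.Memory.B.cells	B.CELL.rWBC	0.731	<0.001	0.000	Strong correlation
xcell.Monocytes	MONOCYTE.rWBC	0.259	<0.001	0.000	Weak correlation
xcell.Naive.B.cells	B.CELL.rWBC	0.786	<0.001	0.000	Strong correlation
xcell.Neutrophils	NEUTROPHIL.rWBC	0.797	<0.001	0.000	Strong correlation
xcell.NK.cells	NK.rWBC	0.411	<0.001	0.000	Moderate correlation
xcell.NKT	NKT.rWBC	-0.252	<0.001	0.000	No or negative correlation
xcell.pDC	PDC.rWBC	0.086	0.187	0.213	No or negative correlation
xcell.Plasma.cells	PLASMABLAST.rWBC	0.520	<0.001	0.000	Strong correlation
xcell.Tgd.cells	GAMMA.DELTA.T.rWBC	0.329	<0.001	0.000	Moderate correlation
xcell.Tregs	TREG.rWBC	0.048	0.461	0.480	No or negative correlation
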