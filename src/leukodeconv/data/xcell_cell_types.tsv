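cell_type	signature_id
aDC	xcell.aDC
Adipocytes	xcell.Adipocytes
Astrocytes	xcell.Astrocytes
B-cells	xcell.B.cells
Basophils	xcell.Basophils
CD4+ memory T-cells	xcell.CD4.memory.T.cells
CD4+ naive T-cells	xcell.CD4.naive.T.cells
CD4+ T-cells	xcell.CD4.T.cells
CD4+ Tcm	xcell.CD4.Tcm
CD4+ Tem	xcell.CD4.Tem
CD8+ naive T-cells	xcell.CD8.naive.T.cells
CD8+ T-cells	xcell.CD8.T.cells
CD8+ Tcm	xcell.CD8.Tcm
CD8+ Tem	xcell.CD8.Tem
cDC	xcell.cDC
Chondrocytes	xcell.Chondrocytes
Class-switched memory B-cells	xcell.Class.switched.memory.B.cells
CLP	xcell.CLP
CMP	xcell.CMP
DC	xcell.DC
Endothelial cells	xcell.Endothelial.cells
Eosinophils	xcell.Eosinophils
Epithelial cells	xcell.Epithelial.cells
Erythrocytes	xcell.Erythrocytes
Fibroblasts	xcell.Fibroblasts
GMP	xcell.GMP
Hepatocytes	xcell.Hepatocytes
HSC	xcell.HSC
iDC	xcell.iDC
Keratinocytes	xcell.Keratinocytes
ly Endothelial cells	xcell.ly.Endothelial.cells
Macrophages	xcell.Macrophages
Macrophages M1	xcell.Macrophages.M1
Macrophages M2	xcell.Macrophages.M2
Mast cells	xcell.Mast.cells
Megakaryocytes	xcell.Megakaryocytes
Melanocytes	xcell.Melanocytes
Memory B-cells	xcell.Memory.B.cells
MEP	xcell.MEP
Mesangial cells	xcell.Mesangial.cells
Monocytes	xcell.Monocytes
MPP	xcell.MPP
MSC	xcell.MSC
mv Endothelial cells	xcell.mv.Endothelial.cells
Myocytes	xcell.Myocytes
naive B-cells	xcell.Naive.B.cells
Neurons	xcell.Neurons
Neutrophils	xcell.Neutrophils
NK cells	xcell.NK.cells
NKT	xcell.NKT
Osteoblast	xcell.Osteoblast
pDC	xcell.pDC
Pericytes	xcell.Pericytes
Plasma cells	xcell.Plasma.cells
Platelets	xcell.Platelets
Preadipocytes	xcell.Preadipocytes
pro B-cells	xcell.pro.B.cells
Sebocytes	xcell.Sebocytes
Skeletal muscle	xcell.Skeletal.muscle
Smooth muscle	xcell.Smooth.muscle
Tgd cells	xcell.Tgd.cells
Th1 cells	xcell.Th1.cells
Th2 cells	xcell.Th2.cells
Tregs	xcell.Tregs
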