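Chondrocytes
Osteoblast
Myocytes
Keratinocytes
Hepatocytes
Endothelial cells
Astrocytes
Adipocytes
Epithelial cells
mv Endothelial cells
Neurons
Pericytes
Preadipocytes
Skeletal muscle
Sebocytes
Mesangial cells
Melanocytes
ly Endothelial cells
Smooth muscle
Fibroblasts
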