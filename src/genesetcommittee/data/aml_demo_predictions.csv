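expert_id,classifier,gene_set,AP13058,AP14398,AP5204,BP7644,CP13774,CP9949,XP12570,XP15833,XP170,XP17273,XP6209,XP9875
DT#1,Decision Tree,Positive regulation of phosphatidylinositol 3-kinase cascade,LAP,LAP,LAP,OTH,M5,M5,OTH,M5,OTH,LAP,INV,INV
DT#2,Decision Tree,Positive regulation of protein phosphorylation,LAP,LAP,INV,INV,M5,M5,OTH,LAP,OTH,LAP,OTH,OTH
DT#3,Decision Tree,Positive regulation of tumor necrosis factor production,LAP,OTH,LAP,INV,M5,M5,OTH,M5,OTH,OTH,LAP,OTH
DT#4,Decision Tree,Regulation of cell shape,LAP,LAP,LAP,INV,M5,M5,M5,M5,OTH,LAP,LAP,OTH
NBS#1,Naive Bayes,Positive regulation of phosphatidylinositol 3-kinase cascade,LAP,LAP,LAP,OTH,OTH,M5,OTH,OTH,OTH,OTH,OTH,OTH
NBS#2,Naive Bayes,Regulation of cell shape,LAP,LAP,LAP,OTH,OTH,M5,OTH,OTH,OTH,OTH,OTH,OTH
RF#1,Random Forest,Regulation of cell shape,LAP,LAP,LAP,INV,M5,M5,M5,OTH,OTH,OTH,OTH,OTH
IBK#1,k-Nearest Neighbours,Phagocytosis,LAP,LAP,LAP,INV,M5,M5,M5,LAP,OTH,OTH,INV,M5
IBK#2,k-Nearest Neighbours,Protein homotetramerization,OTH,LAP,LAP,INV,INV,M5,OTH,OTH,OTH,OTH,OTH,OTH
IBK#3,k-Nearest Neighbours,Regulation of cell shape,LAP,LAP,LAP,INV,M5,M5,INV,OTH,INV,OTH,OTH,OTH
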