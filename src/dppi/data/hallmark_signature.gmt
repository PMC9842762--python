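P1	GO:0035722|interleukin-12-mediated signalling pathway|GO_BiologicalProcess	LCP1	PPIA	S100A9
P2	GO:0035987|endodermal cell differentiation|GO_BiologicalProcess	FN1	MMP8	MMP9
P3	GO:0043394|proteoglycan binding|GO_MolecularFunction	AZU1	CFH	CTSB	FN1	HRG	LCP1	NID1
P4	GO:0004601|peroxidase activity|GO_BiologicalProcess	CAT	HBA1	HBB	HBD	MPO
P5	R-HSA:166658|Complement cascade|REACTOME_Pathways	C3	C4A	C9	CD55	CFH	F2
P6	GO:0006959|humoral immune response|GO_BiologicalProcess	A2M	APCS	AZU1	C3	C4A	C9	CAMP	CD55	CFH	F2	FGB	HPX	HRG	IGHG1	IGKV2D-30	KRT1	LCN2	LTF	LYZ	PRTN3	S100A9
P7	R-HSA:6802957|Oncogenic MAPK signalling|REACTOME_Pathways	FGB	FGG	FN1
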