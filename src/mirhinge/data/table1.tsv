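mirna	gene_symbol	gene_name	identification_method
hsa-mir-192	FGF2	Fibroblast Growth Factor 2	Combined Model
hsa-mir-192	ITGAV	integrin subunit alpha V	Combined Model
hsa-mir-192	LOXL2	lysyl oxidase-like 2	Combined Model
hsa-mir-192	ITGB1	integrin subunit beta 1	Combined Model
hsa-mir-192	PLOD1	procollagen-lysine, 2-oxoglutarate 5-dioxygenase 1	Combined Model
hsa-mir-192	PXDN	peroxidasin	Combined Model
hsa-mir-192	SPARC	Secreted Protein Acidic And Cysteine Rich	Combined Model
hsa-mir-192	DST	Dystonin	Combined Model
hsa-mir-192	FBN1	Fibrillin 1	Combined Model
hsa-mir-192	FN1	Fibronectin 1	Binding site analysis
hsa-mir-192	KDR	Kinase Insert Domain Receptor	Binding site analysis
hsa-mir-192	MMP2	Matrix Metallopeptidase 2	Binding site analysis
hsa-mir-192	TGFB1	Transforming Growth Factor Beta 1	Binding site analysis
hsa-mir-200c	ETS1	ETS Proto-Oncogene 1	Combined Model
hsa-mir-200c	KDR	Kinase Insert Domain Receptor	Combined Model
hsa-mir-200c	SERPINH1	Serpin Family H Member 1	Combined Model
hsa-mir-200c	TIMP2	TIMP Metallopeptidase Inhibitor 2	Combined Model
hsa-mir-200c	NCAM1	Neural Cell Adhesion Molecule 1	Combined Model
hsa-mir-200c	FN1	Fibronectin 1	Combined Model
hsa-mir-200c	FBLN5	Fibulin 5	Combined Model
hsa-mir-200c	DST	Dystonin	Binding site analysis
hsa-mir-200c	FGF2	Fibroblast Growth Factor 2	Binding site analysis
hsa-mir-200c	ITGAV	integrin subunit alpha V	Binding site analysis
hsa-mir-200c	ITGB1	integrin subunit beta 1	Binding site analysis
hsa-mir-200c	PLOD1	procollagen-lysine, 2-oxoglutarate 5-dioxygenase 1	Binding site analysis
hsa-mir-200c	SPARC	Secreted Protein Acidic And Cysteine Rich	Binding site analysis
hsa-mir-17	MMP2	Matrix Metallopeptidase 2	Combined Model
hsa-mir-17	FSCN1	Fascin Actin-Bundling Protein 1	Combined Model
hsa-mir-17	LAMC1	Laminin Subunit Gamma 1	Combined Model
hsa-mir-17	TGFB1	Transforming Growth Factor Beta 1	Combined Model
hsa-mir-17	DST	Dystonin	Binding site analysis
hsa-mir-17	ETS1	ETS Proto-Oncogene 1	Binding site analysis
hsa-mir-17	FBN1	Fibrillin 1	Binding site analysis
hsa-mir-17	FGF2	Fibroblast Growth Factor 2	Binding site analysis
hsa-mir-17	FN1	Fibronectin 1	Binding site analysis
hsa-mir-17	ITGAV	integrin subunit alpha V	Binding site analysis
hsa-mir-17	ITGB1	integrin subunit beta 1	Binding site analysis
hsa-mir-17	PXDN	peroxidasin	Binding site analysis
hsa-mir-17	TIMP2	TIMP Metallopeptidase Inhibitor 2	Binding site analysis
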