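node_type	name	degree
miRNA	hsa-miR-494	22
miRNA	hsa-miR-183	14
miRNA	hsa-miR-96	11
miRNA	hsa-miR-374a	10
miRNA	hsa-miR-21	6
miRNA	hsa-miR-455-3p	6
miRNA	hsa-miR-542-3p	6
miRNA	hsa-miR-490-5p	5
miRNA	hsa-miR-15b	4
miRNA	hsa-miR-7	4
miRNA	hsa-let-7f	3
miRNA	hsa-miR-98	3
miRNA	hsa-miR-192	2
miRNA	hsa-miR-34b	2
miRNA	hsa-miR-375	2
GO	Regulation of transcription, DNA-dependent	12
GO	Transcription	9
GO	Development	8
GO	Signal transduction	6
GO	Apoptosis	5
GO	Cell differentiation	5
GO	Cell cycle	4
GO	Cell cycle arrest	4
GO	Cell division	4
GO	Negative regulation of progression through cell cycle	3
GO	Positive regulation of transcription from RNA polymerase II promoter	3
GO	Rhythmic process	3
GO	Cell aging	2
GO	Cytokinesis	2
GO	Negative regulation of JNK activity	2
GO	Negative regulation of transcription from RNA polymerase II promoter	2
GO	Organic anion transport	2
GO	Protein amino acid phosphorylation	2
GO	Response to hypoxia	2
GO	Transcription from RNA polymerase II promoter	2
GO	Actin modification	1
GO	Cell dedifferentiation	1
GO	Cellular response to insulin stimulus	1
GO	Chromatin remodeling	1
GO	G1 phase of mitotic cell cycle	1
GO	Glucose homeostasis	1
GO	Insulin-like growth factor receptor signaling pathway	1
GO	Leukemia inhibitory factor signaling pathway	1
GO	NAD metabolism	1
GO	Negative regulation of epithelial cell proliferation	1
GO	Negative regulation of insulin-like growth factor receptor signaling pathway	1
GO	Phosphoinositide 3-kinase cascade	1
GO	Positive regulation of fibroblast proliferation	1
GO	Positive regulation of glucose import	1
GO	Positive regulation of mitotic metaphase/anaphase transition	1
GO	Protein kinase B signaling cascade	1
GO	Response to cytokine stimulus	1
GO	Response to peptide hormone stimulus	1
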