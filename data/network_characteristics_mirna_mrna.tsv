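node_type	name	degree
miRNA	hsa-miR-494	14
miRNA	hsa-miR-96	11
miRNA	hsa-miR-455-3p	8
miRNA	hsa-miR-542-3p	7
miRNA	hsa-miR-183	6
miRNA	hsa-miR-374a	6
miRNA	hsa-miR-375	5
miRNA	hsa-miR-21	4
miRNA	hsa-miR-7	4
miRNA	hsa-miR-148a	3
miRNA	hsa-miR-192	3
miRNA	hsa-miR-221	3
miRNA	hsa-miR-34b	3
miRNA	hsa-miR-490-5p	3
miRNA	hsa-let-7f	2
miRNA	hsa-miR-15b	2
miRNA	hsa-miR-424	2
miRNA	hsa-miR-454	1
miRNA	hsa-miR-98	1
mRNA	RUNX1T1	3
mRNA	AGPS	2
mRNA	CDK19	2
mRNA	ENAH	2
mRNA	IKZF2	2
mRNA	MAGI1	2
mRNA	MEIS1	2
mRNA	NEBL	2
mRNA	NFIA	2
mRNA	PAQR8	2
mRNA	PDCD4	2
mRNA	PLCXD3	2
mRNA	PLEKHA6	2
mRNA	PTGER3	2
mRNA	RECK	2
mRNA	SESN1	2
mRNA	SH3BGRL2	2
mRNA	SLC16A7	2
mRNA	TACC1	2
mRNA	ATOH8	1
mRNA	C18orf25	1
mRNA	CAPN5	1
mRNA	CBX3	1
mRNA	CCNG2	1
mRNA	CCRN4L	1
mRNA	CDK6	1
mRNA	CHRDL1	1
mRNA	CILP	1
mRNA	CKS1B	1
mRNA	CLPTM1L	1
mRNA	DIAPH2	1
mRNA	ESPL1	1
mRNA	FBXO45	1
mRNA	FCHO2	1
mRNA	GALNT2	1
mRNA	GAS7	1
mRNA	HLF	1
mRNA	IRS1	1
mRNA	ITGA9	1
mRNA	ITPR2	1
mRNA	KIAA0141	1
mRNA	KLB	1
mRNA	LIFR	1
mRNA	LYRM7	1
mRNA	MBNL3	1
mRNA	MRPS23	1
mRNA	MYRIP	1
mRNA	NADK	1
mRNA	NCF2	1
mRNA	NCOA1	1
mRNA	NR2F2	1
mRNA	NTRK3	1
mRNA	PER3	1
mRNA	PHF17	1
mRNA	PLAGL1	1
mRNA	PPFIA1	1
mRNA	RUFY3	1
mRNA	SAMD5	1
mRNA	SLC16A6	1
mRNA	SLC7A11	1
mRNA	SLIT3	1
mRNA	ST3GAL3	1
mRNA	TACR1	1
mRNA	TOR1A	1
mRNA	TRIOBP	1
mRNA	VSIG10	1
mRNA	WDR26	1
mRNA	ZNF281	1
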