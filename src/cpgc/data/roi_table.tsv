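name	network	x	y	z	radius
PCC	DMN	-2	-51	27	12
L pIPL	DMN	-51	-65	27	12
R pIPL	DMN	53	-61	27	12
OFC/vACC	DMN	-2	55	-18	12
dMPFC BA 8	DMN	-16	49	38	12
dMPFC BA 9	DMN	18	54	32	12
L DLPFC	DMN	-44	20	41	12
R DLPFC	DMN	44	20	41	12
L PHG	DMN	-12	-35	0	12
R PHG	DMN	12	-35	0	12
L ITC	DMN	-58	-18	-14	12
R ITC	DMN	58	-18	-14	12
L HF	HCMN	-20	-24	-11	12
R HF	HCMN	21	-18	-16	12
vMPFC	HCMN	-1	46	2	12
PCC	HCMN	0	-54	14	12
L pIPL	HCMN	-45	-70	23	12
R pIPL	HCMN	45	-64	23	12
L MT	DAN	-43	-66	-4	12
R MT	DAN	45	-66	-4	12
L FEF	DAN	-25	-13	48	12
R FEF	DAN	23	14	48	12
L SPL	DAN	-27	-55	50	12
R SPL	DAN	20	-59	49	12
L aPFC	FPCN	-34	51	17	12
R aPFC	FPCN	30	46	18	12
dACC	FPCN	2	25	31	12
L DLPFC	FPCN	-48	14	35	12
R DLPFC	FPCN	41	7	44	12
L aINS	FPCN	-30	18	5	12
R aINS	FPCN	28	19	5	12
L aIPL	FPCN	-50	-51	41	12
R aIPL	FPCN	46	-49	42	12
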