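gene	high_wild	high_wild_pct	high_mut	high_mut_pct	low_wild	low_wild_pct	low_mut	low_mut_pct	p_published
GLRB	192	97.46	5	2.54	221	88.4	29	11.6	0.000653446
ACSM1	192	97.46	5	2.54	226	90.4	24	9.6	0.004861082
ITGAX	194	98.48	3	1.52	231	92.4	19	7.6	0.006359613
SEL1L3	193	97.97	4	2.03	229	91.6	21	8.4	0.006885403
LRRC4C	185	93.91	12	6.09	214	85.6	36	14.4	0.007742623
CATSPERD	178	90.36	19	9.64	242	96.8	8	3.2	0.008300153
MYH4	172	87.31	25	12.69	193	77.2	57	22.8	0.008825349
PKHD1	183	92.89	14	7.11	211	84.4	39	15.6	0.009043977
ATP13A4	188	95.43	9	4.57	220	88	30	12	0.009448039
IGSF10	184	93.4	13	6.6	213	85.2	37	14.8	0.009879668
EXPH5	189	95.94	8	4.06	222	88.8	28	11.2	0.0099167
RXFP2	193	97.97	4	2.03	230	92	20	8	0.010213103
PDGFRA	192	97.46	5	2.54	228	91.2	22	8.8	0.010494566
MPP7	187	94.92	10	5.08	219	87.6	31	12.4	0.012475552
FHDC1	193	97.97	4	2.03	231	92.4	19	7.6	0.015072759
BTBD11	191	96.95	6	3.05	227	90.8	23	9.2	0.015127514
ADGRF4	192	97.46	5	2.54	229	91.6	21	8.4	0.015293351
CSF2RB	192	97.46	5	2.54	229	91.6	21	8.4	0.015293351
TGM6	182	92.39	15	7.61	244	97.6	6	2.4	0.018201576
LRP1B	143	72.59	54	27.41	154	61.6	96	38.4	0.019185781
SZT2	190	96.45	7	3.55	226	90.4	24	9.6	0.020842861
DNAH1	173	87.82	24	12.18	236	94.4	14	5.6	0.021072363
IGHM	192	97.46	5	2.54	230	92	20	8	0.022153014
PPP1R3A	176	89.34	21	10.66	203	81.2	47	18.8	0.02467418
TRPC4	184	93.4	13	6.6	216	86.4	34	13.6	0.02506211
ZNF99	184	93.4	13	6.6	216	86.4	34	13.6	0.02506211
NBEA	182	92.39	15	7.61	213	85.2	37	14.8	0.027528675
PDZD2	185	93.91	12	6.09	218	87.2	32	12.8	0.027530981
PCDHB7	189	95.94	8	4.06	225	90	25	10	0.027672056
FAT4	156	79.19	41	20.81	174	69.6	76	30.4	0.029178661
PLEKHH2	192	97.46	5	2.54	231	92.4	19	7.6	0.031882714
GRM4	193	97.97	4	2.03	233	93.2	17	6.8	0.032281736
CACNA2D4	193	97.97	4	2.03	233	93.2	17	6.8	0.032281736
PTPRB	174	88.32	23	11.68	201	80.4	49	19.6	0.032897855
FCGBP	182	92.39	15	7.61	214	85.6	36	14.4	0.03656706
SI	175	88.83	22	11.17	203	81.2	47	18.8	0.037014862
FLG	158	80.2	39	19.8	178	71.2	72	28.8	0.037794192
PCDHA12	189	95.94	8	4.06	226	90.4	24	9.6	0.038406702
HTT	189	95.94	8	4.06	226	90.4	24	9.6	0.038406702
SERPINB7	180	91.37	17	8.63	241	96.4	9	3.6	0.040168226
ACE	190	96.45	7	3.55	228	91.2	22	8.8	0.041099422
TRPM6	181	91.88	16	8.12	213	85.2	37	14.8	0.043279955
EML5	191	96.95	6	3.05	230	92	20	8	0.043557638
PRLR	187	94.92	10	5.08	223	89.2	27	10.8	0.044684979
SLITRK3	187	94.92	10	5.08	223	89.2	27	10.8	0.044684979
FSIP2	184	93.4	13	6.6	218	87.2	32	12.8	0.044972848
PLCE1	179	90.86	18	9.14	210	84	40	16	0.045282963
ANK3	153	77.66	44	22.34	172	68.8	78	31.2	0.047485414
DNAH10	169	85.79	28	14.21	195	78	55	22	0.047763319
DUOX2	188	95.43	9	4.57	225	90	25	10	0.048733515
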