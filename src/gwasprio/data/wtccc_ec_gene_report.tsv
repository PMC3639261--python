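gene_id	chrom	best_snp	p_add	n_snps
ADCY4	14	rs4981504	4.1E-04	3
GPR116	6	rs2021916	5.4E-04	43
FGD5	3	rs4684243	8.1E-04	23
ARAP3	5	rs6891143	1.0E-03	5
ITGA3	17	rs2269772	1.5E-03	5
DRAM	12	rs10860812	1.8E-03	7
PTPRB	12	rs1867003	3.5E-03	42
SLCO2A1	3	rs10935089	7.7E-03	13
NOTCH4	6	rs415929	1.1E-02	8
TCF21	6	rs3734281	1.3E-02	3
PECAM1	17	rs8074241	1.4E-02	14
CALCRL	2	rs840599	1.4E-02	22
NP_631958	4	rs4365784	1.4E-02	4
NTN4	12	rs7961560	1.4E-02	19
ERG	21	rs2836431	1.7E-02	84
PTPRM	18	rs12457610	1.9E-02	171
RASIP1	19	rs2638283	2.2E-02	2
EHD4	15	rs1002774	2.5E-02	12
Q8IW82	5	rs6882738	3.4E-02	14
ITGA8	10	rs17137406	3.4E-02	65
NRP1	10	rs870087	3.6E-02	45
COL4A3	2	rs11677877	3.9E-02	44
ELTD1	1	rs2035727	4.2E-02	15
NUMB	14	rs7148830	4.7E-02	18
NPR3	5	rs696833	5.1E-02	18
PALD	10	rs16927685	6.0E-02	32
AGER	6	rs1035798	7.6E-02	1
MYO1B	2	rs897196	8.3E-02	35
CBFA2T3	16	rs519507	8.9E-02	6
DTR	5	rs4150212	9.3E-02	5
ENTPD1	10	rs10882664	9.5E-02	18
MMRN2	10	rs12416136	1.2E-01	1
NP_079106	5	rs27059	1.4E-01	15
SOX7	8	rs7009920	1.5E-01	2
CDH5	16	rs8051913	1.5E-01	6
LRRK1	15	rs7163635	1.6E-01	4
NP_061174	1	rs1175645	1.6E-01	18
C20orf160	20	rs6061095	1.6E-01	1
PSCD3	7	rs7777433	1.6E-01	7
EPAS1	2	rs10191091	1.8E-01	23
SMAD6	15	rs16950159	1.8E-01	12
TIE	1	rs1467809	2.3E-01	1
ROBO4	11	rs12823	2.4E-01	3
SLC43A3	11	rs3851116	2.4E-01	2
NP_938019	4	rs17036363	2.4E-01	4
TENC1	12	rs2364153	2.5E-01	3
PLTP	20	rs1736493	2.5E-01	2
KDR	4	rs17085310	2.8E-01	5
SOX13	1	rs12092337	2.9E-01	3
ACVRL1	12	rs7956340	3.3E-01	3
EPHB4	7	rs314313	3.3E-01	1
LATS2	13	rs11841745	3.3E-01	19
VEGF	6	rs3025047	3.5E-01	2
CCBP2	3	rs6763528	3.7E-01	4
ICAM2	17	rs4141180	4.1E-01	1
NP_940873	19	rs1019757	4.6E-01	2
CASKIN2	17	rs4789205	4.6E-01	3
ESAM	11	rs7928640	6.4E-01	3
STARD9	15	rs16957063	6.5E-01	4
HSPA12B	20	rs3088007	7.6E-01	1
SDPR	2	rs4280394	8.0E-01	1
ENG	9	rs11792480	8.1E-01	2
ICAM1	19	n/a	n/a	0
CLDN5	22	n/a	n/a	0
Q8TAY7	1	n/a	n/a	0
EGFL7	9	n/a	n/a	0
SLC9A3R2	16	n/a	n/a	0
NP_078855	1	n/a	n/a	0
RAMP2	17	n/a	n/a	0
HIG2_HUMAN	7	n/a	n/a	0
NP_115724	1	n/a	n/a	0
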