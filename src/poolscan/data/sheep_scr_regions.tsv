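# 32 selected candidate regions reported for Western Pyrenees sheep
# (Sasi Ardi = SAS-specific group A; shared by the two Latxa populations =
# group B; Latxa improvement-program contrast LAS vs LAN = group C).
# Coordinates are core spans in kb on Ovis aries autosomes.
# Group B region 20 on chromosome 6 is the merge of three continuous
# stretches: 36,450-37,000 kb, 37,050-38,100 kb and 38,200-38,400 kb.
group	scr	chrom	start_kb	end_kb	n_genes
A	1	2	219400	219650	14
A	2	3	182650	183050	5
A	3	4	35150	35350	2
A	4	4	63050	63250	3
A	5	6	24650	24950	7
A	6	6	44750	45000	7
A	7	6	48300	48500	3
A	8	7	42000	42250	5
A	9	8	7950	8300	0
A	10	8	31900	32250	4
A	11	8	90100	90300	6
A	12	11	18300	18550	5
A	13	19	29600	29800	1
A	14	20	15050	15300	11
A	15	22	22050	22250	15
A	16	24	10250	10500	10
B	17	1	234800	235000	8
B	18	2	115000	115200	0
B	19	3	124800	125000	1
B	20	6	36450	38400	19
B	21	7	72550	72600	7
B	22	18	23600	23850	3
B	23	19	43300	43500	5
B	24	24	34650	34800	6
C	25	2	202050	202350	12
C	26	8	75350	75550	1
C	27	11	18350	18550	5
C	28	13	350	550	0
C	29	13	58750	58950	14
C	30	15	46150	46350	20
C	31	16	9050	9350	6
C	32	22	29050	29250	2
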