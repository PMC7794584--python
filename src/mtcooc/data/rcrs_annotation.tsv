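gene	start	end	kind
CR	16024	16569	control_region
CR	1	576	control_region
MT-TF	577	647	tRNA
MT-RNR1	648	1601	rRNA
MT-TV	1602	1670	tRNA
MT-RNR2	1671	3229	rRNA
MT-TL1	3230	3304	tRNA
MT-ND1	3307	4262	protein
MT-TI	4263	4331	tRNA
MT-TQ	4329	4400	tRNA
MT-TM	4402	4469	tRNA
MT-ND2	4470	5511	protein
MT-TW	5512	5579	tRNA
MT-TA	5587	5655	tRNA
MT-TN	5657	5729	tRNA
MT-TC	5761	5826	tRNA
MT-TY	5826	5891	tRNA
MT-CO1	5904	7445	protein
MT-TS1	7446	7514	tRNA
MT-TD	7518	7585	tRNA
MT-CO2	7586	8269	protein
MT-TK	8295	8364	tRNA
MT-ATP8	8366	8572	protein
MT-ATP6	8527	9207	protein
MT-CO3	9207	9990	protein
MT-TG	9991	10058	tRNA
MT-ND3	10059	10404	protein
MT-TR	10405	10469	tRNA
MT-ND4L	10470	10766	protein
MT-ND4	10760	12137	protein
MT-TH	12138	12206	tRNA
MT-TS2	12207	12265	tRNA
MT-TL2	12266	12336	tRNA
MT-ND5	12337	14148	protein
MT-ND6	14149	14673	protein
MT-TE	14674	14742	tRNA
MT-CYB	14747	15887	protein
MT-TT	15888	15953	tRNA
MT-TP	15956	16023	tRNA
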