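name	chrom	start	end
1p	chr1	0	121535434
1q	chr1	124535434	249250621
2p	chr2	0	92326171
2q	chr2	95326171	243199373
3p	chr3	0	90504854
3q	chr3	93504854	198022430
4p	chr4	0	49660117
4q	chr4	52660117	191154276
5p	chr5	0	46405641
5q	chr5	49405641	180915260
6p	chr6	0	58830166
6q	chr6	61830166	171115067
7p	chr7	0	58054331
7q	chr7	61054331	159138663
8p	chr8	0	43838887
8q	chr8	46838887	146364022
9p	chr9	0	47367679
9q	chr9	50367679	141213431
10p	chr10	0	39254935
10q	chr10	42254935	135534747
11p	chr11	0	51644205
11q	chr11	54644205	135006516
12p	chr12	0	34856694
12q	chr12	37856694	133851895
13p	chr13	0	16000000
13q	chr13	19000000	115169878
14p	chr14	0	16000000
14q	chr14	19000000	107349540
15p	chr15	0	17000000
15q	chr15	20000000	102531392
16p	chr16	0	35335801
16q	chr16	38335801	90354753
17p	chr17	0	22263006
17q	chr17	25263006	81195210
18p	chr18	0	15460898
18q	chr18	18460898	78077248
19p	chr19	0	24681782
19q	chr19	27681782	59128983
20p	chr20	0	26369569
20q	chr20	29369569	63025520
21p	chr21	0	11288129
21q	chr21	14288129	48129895
22p	chr22	0	13000000
22q	chr22	16000000	51304566
Xp	chrX	0	58632012
Xq	chrX	61632012	155270560
Yp	chrY	0	10104553
Yq	chrY	13104553	59373566
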