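# Per-comparison candidate selection-signature intervals reported by a
# published genome-wide fat-tail vs thin-tail sheep scan (six pair-wise
# breed comparisons, Illumina OvineSNP50, Oar_v4.0 assembly).
# Coordinates: 1-based inclusive bp.  comparison: 1=Ethiopian fat-tail,
# 2=Ethiopian long fat-tail, 3=Arabian peninsula fat-tail, 4=Barbaresca,
# 5=Laticauda, 6=Libyan Barbary (each vs its regional thin-tail group).
# row_id groups intervals printed on the same table row.
row_id	chrom	comparison	start_bp	end_bp
1	3	3	104333496	105210346
1	3	6	104291439	105909563
2	3	5	154458718	156011304
2	3	6	155014204	155055875
3	5	1	48226104	48526532
3	5	2	46925830	49273852
4	6	4	38104576	39576650
4	6	5	38179178	39639829
5	6	1	55697868	55794685
5	6	2	55697868	55811685
6	6	1	75842854	76599033
6	6	5	75533914	75941134
7	6	1	80325742	80531786
7	6	6	80878591	80912095
8	7	4	33736820	33937483
8	7	5	33565208	33841590
9	10	1	40258505	45063369
9	10	2	40594254	45416672
9	10	5	40957582	45416672
9	10	6	42194236	45155143
10	12	5	43000381	43168807
10	12	6	43168807	43297179
11	13	5	46565715	49137513
11	13	6	47583113	49208171
12	17	1	61094671	61631272
12	17	6	61496170	61658381
13	18	1	1895285	2129462
13	18	2	1980832	2243903
14	19	1	51617073	51789681
14	19	2	51649648	51819178
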