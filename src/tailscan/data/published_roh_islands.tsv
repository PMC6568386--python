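# ROH islands per breed/group reported by the same published fat-tail vs
# thin-tail sheep scan (top-0.9999 locus-homozygosity percentile within each
# group; Oar_v4.0).  Coordinates: 1-based inclusive bp.
group	tail_type	chrom	n_snps	start_bp	end_bp
Ethiopian_fat	fat	5	17	48278057	49199542
Ethiopian_fat	fat	10	34	36757445	39446610
Ethiopian_long_fat	fat	5	29	47692576	49199542
Arabian_fat	fat	2	8	131264212	131695396
Arabian_fat	fat	2	11	135482289	136005787
Arabian_fat	fat	4	25	26305564	27655062
Barbaresca	fat	6	48	34851127	38495020
Laticauda	fat	3	7	13571685	13899340
Libyan_Barbary	fat	2	12	113637672	114513743
Libyan_Barbary	fat	7	76	94404153	98581328
Sudan	thin	1	9	198471933	198933003
Sidaoun	thin	2	5	38190022	38368173
Sidaoun	thin	2	35	38827516	40453440
Sidaoun	thin	13	17	35563319	36504021
Italian_thin	thin	2	64	71595057	75092467
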