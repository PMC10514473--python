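snp_id	chrom	bp	beta	se	pval	f_reported
chr1:169549040	1	169549040	0.256626	0.0526221	5.38E-17	23.78290813
chr3:160301772	3	160301772	0.173412	0.0382163	6.83E-10	20.59022153
chr4:103468518	4	103468518	0.231341	0.0355169	9.21E-13	42.42629546
chr5:1285974	5	1285974	0.254141	0.0408623	3.58E-09	38.68154864
chr6:31196862	6	31196862	0.26506	0.0390643	6.07E-09	46.03925573
chr7:130416394	7	130416394	-0.288833	0.047146	3.71E-13	37.53219107
chr9:6448912	9	6448912	0.230314	0.0396861	1.96E-09	33.67936009
chr10:38216363	10	38216363	-0.355469	0.0566447	1.91E-17	39.38083341
chr10:49675247	10	49675247	-0.290248	0.0364699	7.26E-11	63.33872644
chr10:98052109	10	98052109	-0.536137	0.0727629	1.91E-17	54.29146493
chr11:66076360	11	66076360	0.163407	0.0367681	5.79E-10	19.75144789
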