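protein_name	accession	peptide	precursor_charge	precursor_mz	product_series	product_index	product_charge	product_mz	cys_ethanolyl	detected	observed_fold_change
Proenkephalin-A	P01210	ELLQLSKPELPQDGTSTLR	2	1063.7	y	6	1	634.4	0	1	2.57
Proenkephalin-A	P01210	ELLQLSKPELPQDGTSTLR	2	1063.7	y	9	1	974.5	0	1	2.57
Proenkephalin-A	P01210	ELLQLSKPELPQDGTSTLR	2	1063.7	y	12	1	1313.7	0	1	2.57
Isoform 1 of Extracellular matrix protein 1	Q16610	QHVVYGPWNLPQSSYSHLTR	3	790.9	y	10	2	588.3	0	1	1.19
Isoform 1 of Extracellular matrix protein 1	Q16610	QHVVYGPWNLPQSSYSHLTR	3	790.9	y	15	2	871.9	0	1	1.19
Isoform 1 of Extracellular matrix protein 1	Q16610	QHVVYGPWNLPQSSYSHLTR	3	790.9	y	16	2	953.5	0	1	1.19
Secretogranin 2	P13521	IESQTQEEVR	2	610.1	y	8	2	488.7	0	1	1.54
Secretogranin 2	P13521	IESQTQEEVR	2	610.1	y	8	1	976.5	0	1	1.54
Secretogranin 2	P13521	VLEYLNQEK	2	568.6	y	6	1	794.4	0	1	1.54
Secretogranin 2	P13521	VLEYLNQEK	2	568.6	y	7	1	923.4	0	1	1.54
Insulin-like growth factor binding protein 7	Q16270	ITVVDALHEIPVK	3	478.9	y	10	2	560.8	0	1	-3.38
Insulin-like growth factor binding protein 7	Q16270	ITVVDALHEIPVK	3	478.9	y	11	2	610.4	0	1	-3.38
Insulin-like growth factor binding protein 7	Q16270	ITVVDALHEIPVK	3	478.9	y	12	2	660.9	0	1	-3.38
Insulin-like growth factor binding protein 7	Q16270	AGAAAGGPGVSGVCVCK	2	746.9	y	7	1	783.4	1	1	-3.38
Insulin-like growth factor binding protein 7	Q16270	AGAAAGGPGVSGVCVCK	2	746.9	y	10	1	1036.5	1	1	-3.38
Insulin-like growth factor binding protein 7	Q16270	AGAAAGGPGVSGVCVCK	2	746.9	y	12	1	1150.6	1	1	-3.38
Isoform 1 of CD166 antigen	Q13740	SSPSFSSLHYQDAGNYVCETA	2						1	0	
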