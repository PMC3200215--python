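protein_name	priority	accession	peptide	confidence	fold_change
Proenkephalin-A	1	P01210	LVRPADINFLACVMECEGKLPSLK	99.99	1.29
Proenkephalin-A	1	P01210	AEEDDSLANSSDLLKELLETGDNR	99.99	1.29
Proenkephalin-A	1	P01210	ECSQDCATCSYR	93.45	1.29
Proenkephalin-A	1	P01210	ELLETGDNR	99.31	1.29
Proenkephalin-A	1	P01210	ELLQLSKPELPQDGTSTLR	99.23	1.29
Isoform 1 of Extracellular matrix protein 1	1	Q16610	FSCFQEEAPQPHYQLR	99.99	1.42
Isoform 1 of Extracellular matrix protein 1	1	Q16610	QHVVYGPWNLPQSSYSHLTR	99.99	1.42
Isoform 1 of Extracellular matrix protein 1	1	Q16610	NIWRDPALCCYLSPGDEQVNCFNINYLR	99.99	1.42
Isoform 1 of Extracellular matrix protein 1	1	Q16610	ACPSHQPDISSGLELPFPPGVPTLDNIK	99.99	1.42
Secretogranin 2	1	P13521	IESQTQEEVR	99.99	1.35
Secretogranin 2	1	P13521	TNEIVEEQYTPQSLATLESVFQELGK	99.99	1.35
Secretogranin 2	1	P13521	VLEYLNQEK	99.99	1.35
Secretogranin 2	1	P13521	GQGSSEDDLQEEEQIEQAIK	99.99	1.35
Secretogranin 2	1	P13521	EHLNQGSSQETDKLAPVS	99.99	1.35
Secretogranin 2	1	P13521	ALEYIENLR	90.56	1.35
Secretogranin 2	1	P13521	QYWDEDLLMK	99.73	1.35
Isoform 1 of CD166 antigen	1	Q13740	SSPSFSSLHYQDAGNYVCETALQEVEGLK	99.99	1.52
Isoform 1 of CD166 antigen	1	Q13740	ALFLETEQLK	91.12	1.52
Insulin-like growth factor binding protein 7	1	Q16270	ITVVDALHEIPVK	99.99	-1.46
Insulin-like growth factor binding protein 7	1	Q16270	SSSDTCGPCEPASCPPLPPLGCLLGETR	99.99	-1.46
Insulin-like growth factor binding protein 7	1	Q16270	SRYPVCGSDGTTYPSGCQLR	99.99	-1.46
Insulin-like growth factor binding protein 7	1	Q16270	TELLPGDRDNLAIQTR	99.98	-1.46
Insulin-like growth factor binding protein 7	1	Q16270	EDAGEYECHASNSQGQASASAK	99.99	-1.46
Insulin-like growth factor binding protein 7	1	Q16270	AGAAAGGPGVSGVCVCK	99.99	-1.46
Insulin-like growth factor binding protein 7	1	Q16270	GTCEQGPSIVTPPK	99.50	-1.46
SPARC	1	P09486	YIPPCLDSELTEFPLR	99.99	-1.47
SPARC	1	P09486	APLIPMEHCTTR	99.96	-1.47
SPARC	1	P09486	PPCLDSELTEFPLR	99.52	-1.47
SPARC	1	P09486	RLEAGDHPVELLAR	99.99	-1.47
Neurosecretory protein VGF	1	O15240	GRPEAQPPPLSSEHKEPVAGDAVPGPK	99.99	1.42
Neurosecretory protein VGF	1	O15240	LADLASDLLLQYLLQGGAR	99.99	1.42
Neurosecretory protein VGF	1	O15240	ESAREEEEAEQER	99.99	1.42
Neurosecretory protein VGF	1	O15240	NSEPQDEGELFQGVDPR	99.99	1.42
Neurosecretory protein VGF	1	O15240	RPESALLGGSEAGER	99.99	1.42
Neurosecretory protein VGF	1	O15240	THLGEALAPLSK	99.99	1.42
Neurosecretory protein VGF	1	O15240	VGEEDEEAAEAEAEAEEAER	99.99	1.42
Neurosecretory protein VGF	1	O15240	LLQQGLAQVEAGR	99.99	1.42
Neurosecretory protein VGF	1	O15240	NAPPEPVPPPR	99.99	1.42
Neurosecretory protein VGF	1	O15240	GLQEAAEER	95.27	1.42
Neurosecretory protein VGF	1	O15240	FGEGVSSPK	99.99	1.42
Neurosecretory protein VGF	1	O15240	AYQGVAAPFPK	99.99	1.42
TPP1	1	B5MDC1	YLTLENVADLVRPSPLTLHTVQK	98.74	-1.44
TPP1	1	B5MDC1	VPIPWVSGTSASTPVFGGILSLINEHR	99.99	-1.44
Neurocan core protein	1	O14594	GIEDEQDLVPLEVTGVVFHYR	99.99	1.30
Neurocan core protein	1	O14594	RNPQELYDVYCFAR	99.99	1.30
Neurocan core protein	1	O14594	ELGGEVFYVGPAR	99.99	1.30
Chromogranin A	1	P10645	HSGFEDELSEVLENQSSQAELK	99.99	1.31
Chromogranin A	1	P10645	AEGNNQAPGEEEEEEEEATNTHPPASLPSQK	99.99	1.31
Chromogranin A	1	P10645	GEQEHSQQKEEEEEMAVVPQGLFR	99.07	1.31
Chromogranin A	1	P10645	ELQDLALQGAK	99.99	1.31
Chromogranin A	1	P10645	PQALPEPMQESK	99.99	1.31
Chromogranin A	1	P10645	SEALAVDGAGKPGAEEAQDPEGK	99.99	1.31
Chromogranin A	1	P10645	RPEDQELESLSAIEAELEK	99.99	1.31
Chromogranin A	1	P10645	EDSLEAGLPLQVR	99.99	1.31
Chromogranin A	1	P10645	YPGPQAEGDSEGLSQGLVDREK	99.99	1.31
Chromogranin A	1	P10645	SGELEQEEER	99.99	1.31
Chromogranin A	1	P10645	TDGARPQALPEPMQESK	99.99	1.31
Chromogranin A	1	P10645	GLSAEPGWQAK	99.99	1.31
Cathepsin D	1	P07339	AIGAVPLIQGEYMIPCEK	99.99	-1.37
Cathepsin D	1	P07339	ISVNNVLPVFDNLMQQK	99.99	-1.37
Cathepsin D	1	P07339	FDGILGMAYPR	99.99	-1.37
Cathepsin D	1	P07339	VSTLPAITLK	98.91	-1.37
Cathepsin D	1	P07339	TMSEVGGSVEDLIAK	99.99	-1.37
Cathepsin D	1	P07339	VGFAEAAR	90.97	-1.37
Cathepsin D	1	P07339	LLDIACWIHHK	99.98	-1.37
SOD3	1	P08294	VTEIWQEVMQR	99.99	-1.37
SOD3	1	P08294	LACCVVGVCGPGLWER	99.99	-1.37
SOD3	1	P08294	AGLAASLAGPHSIVGR	96.66	-1.37
SOD3	1	P08294	AVVVHAGEDDLGR	99.99	-1.37
SOD3	1	P08294	RDDDGALHAACQVQPSATLDAAQPR	99.99	-1.37
SOD3	1	P08294	GGNQASVENGNAGR	99.99	-1.37
ENPP2	1	Q13822	NGVNVISGPIFDYDYDGLHDTEDKIK	99.71	-1.36
ENPP2	1	Q13822	YDAFLVTNMVPMYPAFK	99.99	-1.36
ENPP2	1	Q13822	SYTSCCHDFDELCLK	99.99	-1.36
ENPP2	1	Q13822	NKLDELNKR	99.99	-1.36
ENPP2	1	Q13822	RLHYANNR	99.99	-1.36
ENPP2	1	Q13822	VNSMQTVFVGYGPTFK	99.99	-1.36
ENPP2	1	Q13822	DIEHLTSLDFFR	99.99	-1.36
ENPP2	1	Q13822	EIDKIVGQLMDGLK	99.99	-1.36
ENPP2	1	Q13822	TEFLSNYLTNVDDITLVPGTLGR	99.99	-1.36
ENPP2	1	Q13822	RWHVAR	92.27	-1.36
ENPP2	1	Q13822	SCGTHSPYMRPVYPTK	99.99	-1.36
ENPP2	1	Q13822	SYPEILTLK	94.45	-1.36
ENPP2	1	Q13822	QAEVSSVPDHLTSCVRPDVR	99.79	-1.36
ENPP2	1	Q13822	GESHWVDDDCEEIK	99.99	-1.36
ENPP2	1	Q13822	VMPNIEK	94.62	-1.36
ENPP2	1	Q13822	IEDIHLLVER	99.99	-1.36
ENPP2	1	Q13822	VSPSFSQNCLAYK	99.85	-1.36
ENPP2	1	Q13822	KPDQHFKPYLK	99.79	-1.36
ENPP2	1	Q13822	PAVLYR	91.70	-1.36
ENPP2	1	Q13822	PAGFVRPPLIIFSVDGFR	99.99	-1.36
ENPP2	1	Q13822	CFFQGDHGFDNK	90.16	-1.36
ENPP2	1	Q13822	QMSYGFLFPPYLSSSPEAK	99.03	-1.36
Insulin-like growth factor binding protein complex acid labile chain	2	P35858	LAYLQPALFSGLAELR	99.99	-1.45
Caspase recruitment domain-containing protein 14	2	Q9BXL6	GALPGAK	95.91	-1.95
Endothelial cell-selective adhesion molecule	2	Q96AP7	QLPSFQTFFAPALDVIR	99.94	1.95
Isoform 1 of phosphatidylinositol 3-kinase regulatory subunit gamma	2	Q92569	LGEIHDSK	90.36	-2.16
Neutral amino acid transporter B	2	Q15758	SCTVLNVEGDALGAGLLQNYVDR	90.14	-1.87
Isoform 1 of latrophilin-1	2	O94910	TDDKICDADPFQMENVQCYLPDAFK	99.99	1.57
Isoform 1 of histone-lysine N-methyltransferase MLL3	2	Q8NEZ4	IQPPIAQLPIK	91.36	2.03
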