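study	area	climate	growth_form	sg_ratio	samples_per_species	barcodes	resolution_pct
Yulong Mountain FDP, Yunnan, China	25 ha	subalpine temperate	woody and herbaceous	1.49	2.44	rbcL, matK, trnH-psbA, ITS	90
Wytham-Woods, UK	18 ha	temperate	trees	1.00	1.00	rbcL, matK, trnH-psbA, ITS	100
Wabikon-Lake, North America	25.6 ha	temperate	trees	1.25	1.00	rbcL, matK, trnH-psbA	100
SERC, North America	16 ha	temperate	trees	1.33	1.00	rbcL, matK, trnH-psbA	93
Changbaishan FDP, Jilin, China	20 ha	temperate	trees	1.56	1.00	rbcL, matK, trnH-psbA	92
SCBI FDP, America	25.6 ha	temperate	trees	1.75	1.00	rbcL, matK, trnH-psbA	97
Gutianshan FDP, Zhejiang, China	20 ha	subtropical	trees	1.60	1.00	rbcL, matK, trnH-psbA	89
Dinghushan FDP, Guangdong, China	20 ha	subtropical	trees	1.59	1.00	rbcL, matK, trnH-psbA	91
Fushan FDP, Taiwan, China	25 ha	subtropical	trees	1.57	1.00	rbcL, matK, trnH-psbA	85
Lienhuachih FDP, Taiwan, China	25 ha	subtropical	trees	1.71	1.00	rbcL, matK, trnH-psbA	87
Luquillo FDP, New Guinea	16 ha	tropical	trees	1.32	1.00	rbcL, matK, trnH-psbA	92
BCI FDP, Panama	50 ha	tropical	trees	1.64	3.50	rbcL, matK, trnH-psbA	98
Dinghushan nature reserve, Guangdong, China	1133 ha	subtropical	trees	2.04	1.83	rbcL, matK, ITS	94
Ailaoshan nature reserve, Yunnan, China	34483 ha	subtropical	trees	1.84	2.57	rbcL, matK, trnH-psbA, ITS	76
Xishuangbanna nature reserve, Yunnan, China	-	tropical	trees	2.53	3.13	rbcL, matK, trnH-psbA, ITS	60.7
Ontario, Canada	348 ha	temperate	vascular plants	1.47	1.18	rbcL, matK, trnH-psbA	95
Churchill, Canada	20000 ha	arctic	vascular plants	2.12	2.88	rbcL, matK, ITS2	69
Canadian Arctic	-	arctic	vascular plants	2.75	5.40	rbcL, matK	56
Wales, UK	2000000 ha	temperate	seed plants	2.51	3.74	rbcL, matK	74.3
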