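chr20	32434000	32435500	ASXL1	full-gene
chr20	32435800	32440000	ASXL1	full-gene
chr2	25733000	25735000	ASXL2	full-gene
chr2	25740000	25742100	ASXL2	full-gene
chrX	155072000	155073000	BRCC3	full-gene
chr11	119206000	119207400	CBL	full-gene
chr11	119208000	119209300	CBL	full-gene
chr2	25234300	25235800	DNMT3A	full-gene
chr2	25240000	25241300	DNMT3A	full-gene
chr2	25244000	25246500	DNMT3A	full-gene
chr12	22634000	22635400	ETNK1	full-gene
chr20	58909300	58909800	GNAS	hotspot-region
chr20	58839700	58840000	GNAS	hotspot-region
chr1	1806500	1806900	GNB1	hotspot-region
chr2	208248300	208248600	IDH1	hotspot-region
chr15	90088500	90088800	IDH2	hotspot-region
chr9	5069000	5069400	JAK2	hotspot-region
chr9	5073650	5073850	JAK2	hotspot-region
chr4	54657900	54659400	KIT	full-gene
chr4	54723500	54724900	KIT	full-gene
chr12	25245250	25245500	KRAS	hotspot-region
chr12	25227200	25227450	KRAS	hotspot-region
chr1	43349300	43349800	MPL	hotspot-region
chr1	114713850	114714100	NRAS	hotspot-region
chr1	114716050	114716300	NRAS	hotspot-region
chr17	60656500	60658300	PPM1D	full-gene
chr18	44680000	44684800	SETBP1	full-gene
chr2	197400700	197401900	SF3B1	hotspot-region
chr17	76736850	76737150	SRSF2	hotspot-region
chr4	105233900	105237500	TET2	full-gene
chr4	105241300	105243700	TET2	full-gene
chr17	7668400	7670100	TP53	full-gene
chr21	43092500	43093100	U2AF1	hotspot-region
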