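name	sequence	tm
COIpp	TCAACCAACCATAAAGACATCGGCAC	63.2
COIUnR	TAGACTTCTGGGTGGCCRAARAAYCA	64.0
cytbF1	CATGCTAACGGAGCATCCTTCT	60.3
cytbUR	GCAAATAGGAARTATCAYTCRGG	58.0
16sF2	AGTATGRGCGACAGAAAAGGA	56.9
16SR2	GATTCGGTGGTTGGTCCGTTC	61.8
cytbF2	CATATTAAACCCGAATGATATTT	51.7
CRR	GGGAAGAAACAGCATATTATG	54
COI4FU	CTAGGCGACGACCAGATTTATAATGT	60.8
COIR3	ACTCCTGAGGAGGCAAGTAGG	61.8
COIR4U	GTTAGGTCTACTGATGCTCCTGC	62.4
COIR5	GACTGGCAGGGACAGAAGG	61.0
COIIF	CGCCTAAACCAAACAGCATTC	58.4
ATP6R	GTAAAGGTRTAAGGGAGGAG	55.5
ND2Fd	CACCCTAGCTATCCTCCCCCTCATAGC	66.9
ND2Rd	AATAACTTCGGGGAGTCACGAGTGTAGG	65.7
HRMCOIF1	AATGTTATTGTTACAGCACACGC	57.1
HRMCOIR1	GCTATGTCAGGGGCACCAA	58.8
HRMcytbF2	GCAGGCGTAATTATTCTATTAAC	55.3
HRMcytbR1	GGTTTAATATGAGGGGGTGTAAC	58.9
HRM16sF1	GTAAAGATCATAATTAACCCAAG	53.5
HRM16sR1	GTTTGCAGCGGATAGTCTGATAT	58.9
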