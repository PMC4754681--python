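species	primer_name	role	seq	printed_length	printed_tm	target_fragment	note
L. entomophila	21LEnF	F	ACATTGCTGGGTTAGGATTCA	21		188	printed Tm truncated to "56."
L. entomophila	208LEnR-2	R	CTTCCGAACTCTGTAATTTGT	21	54.1	188
L. bostrychophila	LBF	F	CGCACATTGCCGAGCTAGGAT	21	62.3	177
L. bostrychophila	LBR	R	CGCTCCTTGTATTCTCGTTCT	21	58.3	177
L. decolor	164LDeF	F	GAAATGCACTAGAACCGAGA	20	53.5	175
L. decolor	319LDeR	R	ATATATTGAACGTGACGAGT	20	52	175
L. paeta	LPa15F	F	GAACGCACATTGCCGAGTTTT	21	59.7	186
L. paeta	LPa180R	R	ACCGTCCGATGCAGTTACCCTA	22	65.1	186
L. corrodens	LC170F	F	CGAGGAAATCTCACAAGACG	20	55.8	128
L. corrodens	LC277R	R	GTTCTCTACAATCCGTTTGGT	21	55.1	128
L. brunnea	LBr350F	F	ACCGAGATCCTTGTTACGAA	20	57.6	248
L. brunnea	LBr577R	R	GCCGGAATTCTGTTTTACGAG	21	56.4	248
L. rufa	78LRuF-3	F	AATGTTAAATGTCGGAACGCT	21	54.1	199
L. rufa	276LRuR-3	R	TTACGACCTATCGGTACGCTA	21	58	199
L. pearmani	186LPeF	F	ATGCACGAAACGAGAATTCTCA	22	56.3	251
L. pearmani	436LPeR	R	AACGGCTACCATTCTTCAAAC	21	56.3	251
L. mendax	LM60F	F	GTCTGAGGGTCGGTGTTTGCT	21	61.9	185
L. mendax	LM224R	R	AAGTCCGTCAACGCTGCTCTT	21	62.2	185
L. tricolor	LTri20F	F	CACATTGCCGAACTTTGAATT	21	56.4	250
L. tricolor	LTri249R	R	TCTACTATCCGTTTGGTTTAC	21	52.6	250
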