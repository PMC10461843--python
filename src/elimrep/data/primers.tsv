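name	forward	reverse	unit_length
EEEb7	CCGCCAAATGTGTTAGGAATG	CCTGTTGAAAGAGGCCAAAAAC	360
EEEb8	AAAAAAAGGGATTATTGTATATTTTG	CGGTTCGGAATTTTCCAC	47
EEEb9	AAACCCTACAATTGTTCTG	CTCTCCGGTGTGTATTC	84
EEEb10	GTTCTAAATATGGGGCCTACCTT	CATCTTGGCAGAACCCTTTTC	120
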