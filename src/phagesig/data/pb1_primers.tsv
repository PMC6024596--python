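pair_id	forward	reverse	target_cds
1	CTACGGCCGTGCAGAC	CTCCATGTGTGGCATCC	gp10,gp11
2	ACCTTCTTCGGCATCCTC	TGTGGTCACCGTATTCCA	gp23,gp24
3	CGCCATAATAGGCTCCAA	CGAGACATTCGCTGATGA	gp55
4	ACCGACTCACGACGATGG	CGGCAAGGTGTTCGCTTA	gp68,gp69
5	CGTCGAGGATGCTGATGG	GGCAGGTCCGAAGGCTAC	gp84,gp85,gp86
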