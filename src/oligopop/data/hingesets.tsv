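size	fidelity	members	seed
10	0.9985013740006364	AATG,ACAT,CACG,GCTT,GGCA,GTCG,TACA,TGAG,TTAT,TTGC	101
20	0.9782539176344264	AACT,AATG,ACAT,AGAG,AGCA,ATTC,CCAG,CGAT,CGCC,CGTG,CTAA,GACA,GCGA,GCTT,GTGC,GTTG,TAAA,TAGT,TCTG,TGGA	101
30	0.9145293028036299	AATG,ACAT,ACCC,ACGG,AGTT,ATAA,ATTC,CAAC,CCAG,CGAT,CGCT,CGTG,CTTA,GACC,GAGG,GATA,GCCT,GCGA,GCTT,GGAG,GGCA,GTGC,TAGT,TCAA,TCCG,TCTG,TGGG,TGTA,TTAC,TTCT	101
40	0.7243038432899388	AAAT,AATG,ACCT,ACGG,AGAT,AGCA,AGCG,AGTC,ATAA,ATAG,ATTC,CAGA,CCAT,CCGC,CCTA,CGCC,CGGG,CGTC,CGTG,CTCA,CTTG,GAAC,GAGA,GATA,GCAG,GCTT,GGAC,GGGC,GGTA,GTGT,GTTG,TAGT,TCAA,TCCA,TCGC,TCGT,TGTT,TTAC,TTCG,TTTA	101
50	0.5419973051183836	AAAC,AACT,AAGA,AATA,AATG,ACAT,ACCG,ACGC,ACTA,AGAA,AGAC,AGCC,AGGG,ATAG,ATCC,ATGA,CAAC,CACT,CAGA,CATC,CCAG,CCGA,CCGC,CGAT,CGCA,CGTA,CGTG,CTAA,CTCA,GAAG,GAAT,GACC,GAGT,GCAA,GCCG,GCTT,GGCG,GGGA,GGGC,GGTA,GTGC,GTGG,TAAA,TAGG,TCAA,TCCA,TGGT,TGTC,TTAT,TTTG	101
60	0.3767211597428302	AAAC,AAAG,AACT,AATA,AATG,ACAT,ACCC,ACGA,ACGG,AGAT,AGCG,AGGA,ATAA,ATAG,ATCA,CAAA,CAAC,CACA,CAGT,CCAG,CCAT,CCGC,CCTA,CCTG,CGAG,CGCC,CGGC,CGTG,CGTT,GAAA,GAAT,GACC,GAGT,GATA,GATG,GCCC,GCCT,GCGA,GCTT,GGAA,GGAG,GTAG,GTCT,GTGC,TAAG,TACA,TACT,TCAG,TCCG,TCTA,TCTC,TCTT,TGAC,TGCC,TGGG,TGGT,TTCG,TTGC,TTGT,TTTA	101
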