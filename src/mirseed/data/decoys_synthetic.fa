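>rRNA_decoy_01 class=rRNA
AAAGGGGTACGCGAGCAGCGCGTTATTCCGTCTGCAAAAGCAAGCAATAGGTAGAGTAGT
CCGAACGGGGTTATTGGCGGTCTATCGATCAGTAATATCGCGACCTTGCAGATTAAGACA
ACAGAGCTGA
>rRNA_decoy_02 class=rRNA
CCCGAACGGTGTCCGCAACGGGGTTGATGGAGGACAAAACCTTTGCCTCTTCACTTGCCG
AGCCACAATTTACTGCGCCGCACCCAAAGAGAGCTCCAGAGGTACCGAGAGTAGTAGGCA
CCAAGAGAACTCGGTA
>rRNA_decoy_03 class=rRNA
CAAATTGATAGTGGTAGTTACATAGCTGACGACTCCGTAAGACTAACGACGCCCTTTCCG
AGGATGTGTTCCTGATCCGTCTGCTGCAAATTTAGGTATATTCAAGCCCGGTCCGCAGGT
C
>rRNA_decoy_04 class=rRNA
TACAGCGAATACAACCTAACCGGAGTTTACATCTAGAGCATATTCAGAGAGGATGCCGTG
GAGGGCTAGTGACTCTTCCTGACATTGAATTGCTCGGAGCGGTACTTTGGTCCCTTTTAG
GCTTGTCATGAACTAGCTAAGGGTTTGTAATTATAGACCAT
>rRNA_decoy_05 class=rRNA
GATGACGTAAACGACGCAAGTTTATACATGTGATCCTTCGGTCAGGCTTCACTGCGAAGT
AAACGTAATGGAAGCTGAATTCTCTCCATGCATTTAATCGTTACGCGGTATCCGCCCGCA
GTTG
>tRNA_decoy_01 class=tRNA
TGGACTGCCACCTTATATAAGTATCCGCACTGGAGTCGACACCGAGCCGCGGCCCCTGAG
TCATCGAGATGATTGATAGATGAGCGA
>tRNA_decoy_02 class=tRNA
AGCTGTCCTTGTCTAAGCACTAAGAGACGTATCTTCTAAAGGTGTGTCACTTGTGTATGG
ACAGAATCGGAAAGGCGATCATATTCAA
>tRNA_decoy_03 class=tRNA
CTAGGCAAAAGAGGGGGCCGCATCAGGCAGCATACGCCGTCGAGACTTCCAATGGTAAGT
TGGGCGTAGATAACGACGAGGCGGG
>tRNA_decoy_04 class=tRNA
AGAGCGGGCTATACTAGCCTAAGTCTTTAGAACAACACGAGCGGCACGAGCATGTGCGCG
CGTTGTGAAGTACTTCAGTTTTC
>snRNA_decoy_01 class=snRNA
TGCCTATCTGAGTTAGACCACCTACCGTTCCCCCCACCCGATTCTTATTGGCGAAAGCCC
CCTTACCTAATCGTCAGTTGAAGACGTTAGTATGCTGACAATTTT
>snRNA_decoy_02 class=snRNA
AGTCTTACGATCCCACGTTGGATGCAGGGTTCGGTTGCCCCGATTTCATTAAATATTTGG
GCGCAAGGCATGGCTACTCGGCTAATTTGTCTCTGCGCGCTGTTGTATGGCCCAACGTAG
TCCTATTCTCCACTAACCCCGAATGGACGAA
>snoRNA_decoy_01 class=snoRNA
ATTAAGCGTATTCTGCTACCTAAACCATGAATAAATGTGTACTGATCAGAATAGGGCAGA
ACCCTTCTGTTAGAAAGACC
>snoRNA_decoy_02 class=snoRNA
AACGGCCTCTTCGCTCACTTCGAGCAGAGATTGGGACCCAGGGGGCTGATGCACGAAATA
TTCAGTCGGATAAATCATGTTAGTGGAGTGTTA
>other_decoy_01 class=other
AGTTTGCTCGTCGACTAAGTTGCTCCCTTGAACAACGCTAACAATACTGTAATGGTGAAC
CCTTTGTATATATTGTTGCTTGTGAAACGGCA
>other_decoy_02 class=other
ACCGTATCTCGAATGCGATAACCACTTAACCGCGAATGATAATCATTGCGTGATGCTTAA
GTCCGGGAGTACAGTTATAGAATAGTTGCATTCATAGACGGACACGGTAAGGTCAAAATC
CGA
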