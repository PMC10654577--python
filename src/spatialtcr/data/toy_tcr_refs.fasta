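>TRAV1 locus=TRA role=V cys_offset=199
ACAGATCTGCGAAGAAGCAAGCCAGGACGTGTGGGTAGGTTTTGAGTTTGTTCTTTGCCGAAGAACCATGGCGGCCGACGCACGTACATTCAAGTTCCGTTTCGCGAACTCTGGAATTTTCAAATGATACGCTCTCAAGCGAGGATTGCACAATTGAGGGACTCCGTGCCCGAGGTGGTGTGGGGTGGTTGTGTCACTTTGT
>TRAV2 locus=TRA role=V cys_offset=220
GGGCGTATGCATGTCCTTTATGTATTACTGGCTTTGCCAACTAGGATGGGGCGGGAACAGTGTACTCATGGAGGCTATTAGCGTTTGAACATAAACTCAGACCGTTGCATACCCAGGATGAGTGATACTCCGTTCAACCAAGTCGCCCTGGTGAAGAAGTCGTAATTGCCTGCAAGCCGTTATTACTTGCTGCAAGTGTAAGTGGTCCAATTCTAAGTCCTGT
>TRAV3 locus=TRA role=V cys_offset=202
TCTCTTAGGGACCTTACAATGTGCCCCGGATATGGCTGTAAGGAAAGTTCAGCCATCCAACTACCGCAACAACCCCCGCCATCGTGGAAGTTGTACCGTGATGAATGTACTTAGCAGGAAGCTCCTCGCCCCCCATCATAGCTGCCATTTGCCCCGATGTCTCCAAATGCAAGAAGTTTAGTTGTATACTCTCAGATAAACGTGT
>TRAV4 locus=TRA role=V cys_offset=224
GAGGTGCCTCACCAGGATCGACTCGTTGTTCATCTTCAATAGCAGACACTGAGTTAGCCTTGTGAGGATACACCTTGGGTCGCACCGTTACGCATCAATAACCGCTGTCGGCCGTGCAGGATCGTAACGAGCTGGCCGGTGGCGGCACGCGTCGGCCAATAACGGTAAGCCGCACTACGCACCATTGTCCTTTGCGTTGCCACACTGAATCTAATCACGGCATCTGT
>TRAJ1 locus=TRA role=J motif_offset=0
TTTGGCGCATGCTCACGCCTTTGTATAGACATACTACATGAGATGCCCTG
>TRAJ2 locus=TRA role=J motif_offset=0
TTCGGATCTTTCAAAGAGGACTGCCAGGGAGAAACGATCGATGAGCGTAG
>TRAJ3 locus=TRA role=J motif_offset=0
TTTGGGGGCTCGGAAAATCTTACGTATGTGGTTGTAAAGATATGGCATAG
>TRAC1 locus=TRA role=C
CCCCGGCTGCAAGTGGTCGGGCATTTCGTCGGGAGTTCATAAGGCACAACCGTGTAGTAGTCCTCCGATTTCCTGCAGGACAGTGAGAGCTCACCCAGTCAATTCTCAAAACATCGGAGATCAAGTCGGGGTTGTATTTATCGGGCAGGC
>TRAC2 locus=TRA role=C
AAGCGAGGACGTCTTCTTTGCCTATAGATGTGGGGCTCCACCACAAAACCGTGCGCGTACTATCAGGATGTGTTTGATAGTACGTGCGACACTTCCTTCAGGATAAGTGCTCCTGGAGTGTCATAAGTCCTGGTTGATCCGGCTGGTCCC
>TRBV1 locus=TRB role=V cys_offset=203
TGATGCGGTTCCTCAGGGCTCAACTTTTACCATCTTTCGTACCAGCCCATTTTTAGTTAGTTAGGCGTATAGTATGCATGGTCTATAACGTACTTTGATTTTAGAATGTGGCTGATTAATTACACGGAGTCGGGCCGATTAACGAACCATCCAACTTCGCTTCAGTTCTTGCGTATTATCACCCCCAGGTACCAAGACGAGCCTGT
>TRBV2 locus=TRB role=V cys_offset=260
CAAGCCACTATCTCATAAGAACGCTTTATCGTCAGGCGTACCAGCCGTATCTCGCCTACCGAATGGTAGCACACTGCAAATCGATGATTTCGGAGGTTTCGGCCATAGGTGACCCCGGCGATTATCTGCAGCGACTTAGATGCGTCCGATGGTCCGTTAGGCGTTTTCAGATAAGGATGTTCCTGTCATGGCCTGACGGCCGGGGGGAGAGGAGGTGATGATACACAGCTCGACCAGCACGCGGGCTCAGTTTCACGTATTGT
>TRBV3 locus=TRB role=V cys_offset=203
GCAGATTATACGCTAGGCGATAGGATAGGGCGAGCGATGAGCACAGCCAATCCATTTGGGCAAAGCTTCCGCAGATGGGAGATAGAGTATATCTCGACCAGCGCCCTTAATCGGTCGGAGGTACAAGCTTACCCAATCTGGAACATCGGTCACTGGACTAAGGTCTTATGACAGCGGGCCGGATTCCTGCCCCCAGCCAGAATTGT
>TRBV4 locus=TRB role=V cys_offset=257
TCCAAATAGTGCGCATATGCATACATGTGCGCAAGAATCTACCAAAGTTTCGTTAATCCAGATGTGGAGCCGCTCCGTACAAATAAGAAAGGTAACACAACTGATTTGCTGTCGCCCATCGCGCGGCTACACTTTTGTCGCTACGGTTCAGTCACGGTCCTAATTAGTAGGATGGCAAATCCCGACTACGTACCTGTGATAACGAGCGTATTACTCTGTGTGGACCCCTGGACAGCGTAAACCTGTATCGGTAGTACTGT
>TRBJ1 locus=TRB role=J motif_offset=0
TTTGGCACCTTTGGTGAGCGAGAAGGAGTTAACGCCTCATATCTGGCTCT
>TRBJ2 locus=TRB role=J motif_offset=0
TTCGGACGCCGGATCGAGACTGTATATGTTCTACGCTTCGAGTCATACAA
>TRBJ3 locus=TRB role=J motif_offset=0
TTTGGGCGTTGGAGTGTGTCGCCTGTACTTTCGCTACACTTCAGATGTCC
>TRBC1 locus=TRB role=C
GGTAAGGAGGTCAGTGCCAATCGTACGGCGATACCACAAAATGAACCTGTGTGGCTTTAGCCCAGATAGGTGTAGCATACGGGCTGTAAAAGCGTGCACTTACGTTCGACACCGACAATTTTTGGGGATTATCTGTGCGCGGCTCGAACT
>TRBC2 locus=TRB role=C
ACTACCTATGCACGGCGCTCCCCGTTGTTAAGTGTCCGTATCTATATCATTCAAAAATCACGACGTCCGCTAGGCCTAGCAGGTTCAGCGGAAATATGCTGCCCTGTAGTGCGCCGGTCTCACACCACAATGTTGCGGAACTTCCACTGA
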