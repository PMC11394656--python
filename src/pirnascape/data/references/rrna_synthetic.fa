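>syn-rrna-001 synthetic rRNA reference (500 nt)
TCAAGCGCATGCACCCATAATGGAGTATACCTTACCGGTTACTAACTGCCAAATGTTTCCCTAAAGCGGC
GTTTAGCCTATGGTGAACTAGCGGGCCAAAATGATGTCTGTGGGGGTCTAAAAAGAGTAGCGATATCGAT
ATCCGCCTTGTGTTCCAAACCCTTGAACAGTTCGACCGTGCTAACAGGTTACCACCCCATCACATAATTC
GTTCTGGCAAGCACCACATTTGCGCTGACGTCAGGGTGATGAGAACTAGAGCGCTGACGGGGCGAAGTGG
GAACTTGCCACTGGCCGCGCGGGGGCGAGGAAAGGACTGCCTACGTCTCAGGTAGGGATCCGACTTTAAG
GTTAGATTCGGCCAATGGCCGACACGGCTTTCCGACGAATTGCTTAAGGGACAACACTTGGACCAGGGCT
TACCTAAGTTATCGTTCAAAGAGCATAGACATTGAGCTTGCTACGAGCCGTCTGAGTGCGATAAAGGTTG
TGCCCTTCTG
>syn-rrna-002 synthetic rRNA reference (500 nt)
AGAGCAGATTTTGCATTAATGCGTTCTTAGTATATACCTCCTCCTATGAATCGTATCTAGAAACATCTTT
GATTCATGCCAGTCGCTAGGGTGCGGACAGTCAGCGTAAATTCACAATGTACTCGTCGGACAGTTCCGCG
CTTACCCGGCGGTGTGACAGCCCCCACTGACCCAGTGCACCGATTCCGTACGCACGATATCGATGGTTGT
AGCTTTTAATTGTAACGATTAAAGTAGTTTATTTAGTACGCACTAGGGTGTCCCAGAAACTCATTACACG
ATGCGCTCTCTGCCATTGGGGCTTGGTGGGTTTTTGAAAAAGGACCTACAACCCGGGGTGCTATCCACGA
TGCCGGGTTTTGAAGAGGCATGTCTCCGGTCGTTCGCTAATACCGCGGTCCGTTGGACACTGTGTATCGA
CTCACGCAGAGCTCAACGGGCTACGTCCGTAAAATATGATTCAGCCACGATATCCAGATTGTACATTGGC
GCCCGCTTTT
>syn-rrna-003 synthetic rRNA reference (500 nt)
AGCACGACTAATCAATCCTCATCAAGGCATTCGCAGCCTGGAGTTATTTACACTCGAAACGCATTTTGAC
TGCACCCCTTAGTCGCGAAAGCCATGCAGACGTCCGAACCGAACGTTATATTCATACGTTAAGGGCCATT
AATCACGCGACAGTCAGCAACGATCGCCAACTCATAGCGTGGCGGTAGCATTAATCCGTACAAGCTTTTA
TCGAGCAGTTCAGCAGTCACATTCAGGCACAGCTGTCAATGTCGTAGCAGGCAAAGTTAGTAGATCTGAC
TCTTTAGCCTATTTGTAGACACCCGAGTTAGCGGATCGTTCTTTAAAAACGTCATTTTTCAGAAGGGTAT
CTATCATGATAGCGGTTGGATGATCACGAATGGCGATACAGCGGTGAGAACTGTTGTGCTTATTCAGTCT
CCCGATCAGCCGCTTGGTCCGAGCTGGTAGCCCCTTACTGAAGTACCGTGGGGTTTATTGAGGACACCGT
CCGGATCAGA
>syn-rrna-004 synthetic rRNA reference (500 nt)
GGTAAAAACGGGTAATGGAATTGTTACTCTTGTTCCATCACAATTTGGCATAGAACATAGCAATGGTTAT
ACTGTCTAATTGGCGCGCCGTGACCAGCACGTTTACCTGTTATTGACTTGCTAGCCCAGCTGGGTGTAAC
ACCGTTAAAGCATAGAGTAGAAACGCTGGTATTTGCCGTAAGTTACACGTGAGTTAATCGCGGCGCGCTC
GTAGCTCGACTTAAAATATCGATTTTGTCTGCCAAGGTCTGCTAGACGACCAGGTTAATGCACACAGCTC
GAGTCCCTTACGTGATAACATGGTATAAAGCAGGGAATAGAAAGTGCTGTAAAAAAGGATAGTCACAAGG
ATAATATCCGCCCTGTACGTACAACAGATAGTAACAATGGCAGAACTTGAGTGGTGATTTACGGGCTCGA
TGGGCAATTAGTCCAAACACTAGCGCTCATGGCTATGGGTATTACGATCACGATCTGCAGTGACTCGATG
AGGCGGGAGA
>syn-rrna-005 synthetic rRNA reference (500 nt)
TCGCTTTATGTAGAATGTCGGTACGTGCTGCCCAGTTGAACTCATTCCGCCCGAAGGCACTGGAGAACGC
CTACATGCACTACCTCGGTGAAAAATCATCCAGATTTCAGCTATTTACGCAGGACTACTCGTGATACTCT
CAAACAGCTCGTCCTAGTTTGCGGCAGAAACAGTAACTGTGCGTGCGGCCCTAGGGTGAAGGACTCTGAC
TGCCTAGTGCAGGTTGCGATCACCTTCTGGTGTTGTATTTTACGGCCTGCGAAACTAATACAATTTTAGC
TAGACGGAATACACCACCCAGGCTTATGCCGTCATCGACCGATCCCATTCGGGAAACTTGTTCGTTCTCG
GAAAAGATATAGAGTAGCCGTAACATAATTTACGGTATCCTGCGACCCCGTACTGTGACCGAGGCGGCTG
CCCGGAAGGCTATGGCTAACCATATGTCATAATTCCTAAGCATAATCTGGACTGTGAGAATAAGTATTGT
ATAACAGGAC
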