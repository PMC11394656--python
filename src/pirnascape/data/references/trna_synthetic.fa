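>syn-trna-001 synthetic tRNA reference (73 nt)
TCTATTTAAAGTGTAGCTCCAGCCAAACTGTCCGCTTGGAGCGGCTTAGTAACTTGAGTATTTACGGCAG
CCA
>syn-trna-002 synthetic tRNA reference (73 nt)
GAAATGGATGACCTCCAAAGGCGGCGCCCCTCTTTCGCAAATTTTATAGTCCTGCCCGATTACCCACGCA
GGT
>syn-trna-003 synthetic tRNA reference (73 nt)
CACCAGCATTCAAGTAGTAGCAGGCTTGATCCCGCAGTTTAGGTTTACTTACTGTCACTTATGACCATTA
GTA
>syn-trna-004 synthetic tRNA reference (73 nt)
AGTTGTGTTAAAGCTGGAGGTATCGGTGAGGCCGCAAGTTCGTCCGCCGTTGTTCTAATTATCAAGAACC
CAA
>syn-trna-005 synthetic tRNA reference (73 nt)
CGCCTACCGGGGTTTGGTAAAGTTTTGATGCCCTCATTTTGAGTATCTACTGCTGTTCTACACTGATTGC
CAA
>syn-trna-006 synthetic tRNA reference (73 nt)
TAGGGCGAACGGGTCAGTCGGCCATCAAAGTCATATGGGCGTCTTATCTGTATTATATTATTACTTGTAG
TGA
>syn-trna-007 synthetic tRNA reference (73 nt)
TATGGCGCAATGCCGCCGCTATACTAACGGGGCACAAGAGCGCAGAAGTGCGGTATAGGAGTACGAGTTA
AGT
>syn-trna-008 synthetic tRNA reference (73 nt)
CACCTGTTGGGTCACACTGCAGACTCCCCATTGGCTGAATTGTGAAAGGTTACGATTCATATTAATGCGA
AAC
>syn-trna-009 synthetic tRNA reference (73 nt)
GTATGAAGCAGGGCACTGGCCTTACGAACTAGGTTCTAGGGCACGGCTAGTGATAATGAAATTCGCACTC
ACC
>syn-trna-010 synthetic tRNA reference (73 nt)
CAATAAGCAGGGTGACTGGCTGAGATGTTTCGTCAGTAATTGATCGCAACCGCCGTCACATTCATAGGAG
CCC
>syn-trna-011 synthetic tRNA reference (73 nt)
TCATGGCCTCTCCAGCACGAGCTAGGAATAAATGGAACGTCAGCCAATTGGACCAAAGGCAGGGGAATTC
ACA
>syn-trna-012 synthetic tRNA reference (73 nt)
CAAGGCAAAAAGCGGTGTTCCTTGTCAGATTGCCGGCCGGATGGTGCTGGAACACTGCAGAGGGAGCCTG
AAT
>syn-trna-013 synthetic tRNA reference (73 nt)
ATTAATTGGTTTCTCGGGTATACAAGTTAGATTGTATAGTAAGGCTATGTTATATGCGGCCATTCATATC
GGT
>syn-trna-014 synthetic tRNA reference (73 nt)
GCGAGTGGGCATGCATAATTGTTCGTTGTATTCTACGATTTCGCGCAAATTGCTGTGACAGTGGCAAAAG
TTT
>syn-trna-015 synthetic tRNA reference (73 nt)
CCAAGTGCGATACTGTTAATAGACTTATCGACCGAAGAGGATCGTCTCGTTAAAAAGCAGGTGCGCCATG
GCT
>syn-trna-016 synthetic tRNA reference (73 nt)
GCTATGGTTCTCGAATCCTGGTTCCAGAGTAGGCCAATGGGTGAGCGTGCACACACTTCAGTATCAGTCC
TTC
>syn-trna-017 synthetic tRNA reference (73 nt)
TCATCATTGCGAGGCCTAATCCATCGTAAGGGCATACCTAGTGCGAATTGACTTACAGTTAATTGTCCCC
AGA
>syn-trna-018 synthetic tRNA reference (73 nt)
ATACATCCCAGTATCCCGACTGCTCCAAAATAATCCATATCGGGTAAGCGATGTGTCGAGAGTCCCGATT
AGT
>syn-trna-019 synthetic tRNA reference (73 nt)
CTTTTACCGCGTTAGTACACCTTGGTTACAGAACAAACCTATGATTAAGTGACGAGACGGACGGGTAACA
AAT
>syn-trna-020 synthetic tRNA reference (73 nt)
TTGGAGGTTTCTCAAGGTAGAGGGTCCCGCCAGCTTTCCTTCGGCTAGAGATAACTCTCAGCGAGTTCTT
ACA
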