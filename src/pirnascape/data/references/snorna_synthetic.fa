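>syn-snorna-001 synthetic snoRNA reference (90 nt)
TAGGCATTCATCGGTAATACAACACGCCAGGCTCTTGGACCTCGCAAGCGAGGGTGTAATCACTTCTTAG
GGTAGCAGAGTTCATTTTCA
>syn-snorna-002 synthetic snoRNA reference (90 nt)
TAACTCCATAACGGGACAACCAACCGCGCTTTACTCGTATGAACTCTCGGGTCGCGAATTCATATTGTGC
TAGTAGCTGCAGGTGGCCGC
>syn-snorna-003 synthetic snoRNA reference (90 nt)
GTGTACCGGTGACATCCTACCTCCCGCATGGCGTACGATAAACGGGATCTCTAAGTGAACATACCACTTC
AGCTGAGGGTATACCGTACA
>syn-snorna-004 synthetic snoRNA reference (90 nt)
TAGTGTGAGGACGTGGATTAATGTAAGAGCCTTTGTCAAGTTCAATTCAGGAGTCGTAATGGTCGGCGTG
CAGTATTCATAGCATCGTCA
>syn-snorna-005 synthetic snoRNA reference (90 nt)
TATAGAAGGGGGGTCCCGGGGTTAGTACTGTGCCAGGAATGGGTCTGTATAAGTCCCGGATGAGGACCTA
ATTAATTTTATCGGTCCTGA
>syn-snorna-006 synthetic snoRNA reference (90 nt)
CTGCATCATATCCCGACATTGGGGTTAATTGACCGCCATAGATACCTCATGACTTTATCCATGGAGTGTG
TCCACACTTGCATCAACCTT
>syn-snorna-007 synthetic snoRNA reference (90 nt)
TAACAGAAGACTGGCCTTCGAATGGCAATGGCCAATATTGTGGCATACTAATCCATAAAGGGCTTGCTTG
TTGACGACTCAGTCCCGGGT
>syn-snorna-008 synthetic snoRNA reference (90 nt)
CTATTGAACTACTGTTCATACGCAGCCACGGTTGGTTAGGGGTTCCCAGCGCTATAATCTTTCCTCCACC
TCTTGATTCCCCCATGCTCC
>syn-snorna-009 synthetic snoRNA reference (90 nt)
AGCATATGCCGTAGCTAAGACGTGTGGTACTAGATTCATTAAACATTCTAGGACCACATTGTGTTGTTCG
AGCAGTTTGGATCTCCGTGA
>syn-snorna-010 synthetic snoRNA reference (90 nt)
GCAAGGTCCCGAAGGAAAAACCTCGAGTAGGGATCAAGTAGTCACATTGACCATGGTGAGATCGCAAGTG
TCCGGTGAATGCAAGCAGTT
>syn-snorna-011 synthetic snoRNA reference (90 nt)
AGTCGGTACTTAAGCTAGGTAGGGACTAATGTTTCTTCTCGAACATGATGGCTGCGAATTCACACCTAGT
GGGAACGTTTAACAAATTGT
>syn-snorna-012 synthetic snoRNA reference (90 nt)
ATAAATATCAGTACTACCCGCCACTCGGGCTGAGGCACTGCTGTAGAAGGTGTTTTATTCCATAGTCGGT
CAATCTGTTCGATCTGTACG
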