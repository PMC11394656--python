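>syn-snrna-001 synthetic snRNA reference (110 nt)
CGCATTATTGGTTCGATTACCACTGCCTTGATTAGCCACCGAAGCCCCACCTCGTCCAAACCTGGACACA
GTTCTTACGCAAGTGGCTTAAAGCTCAGCCAGGCGGGTGA
>syn-snrna-002 synthetic snRNA reference (110 nt)
CGAATCTACTAGTGATTAGGAAGTTAGGGGGGTCCTGTAGTAGAACTTTGCCACGTATTATATTGCATCG
ACCCCCTGACTCATGCAACGTGGTACCGTCAAGGGTGGTT
>syn-snrna-003 synthetic snRNA reference (110 nt)
ACGACCGGACTTCTCACCCCAATGCATCTATTACGCCCAGCAATGAGACGGGTCAGGTATAGGCGTGAGG
TTTAGCGCGCTAGATAATCTTGACCAGATGCCTTACATTA
>syn-snrna-004 synthetic snRNA reference (110 nt)
GGGGAGGATGACAGGCACAACCTGCCACAAATCACGTGTCAGTCCAAGCATCCGCTCTGTCCGCTCCGAG
ACGCCACGGGTCTCCAGATTTAAGCTTAATGTGGGTGGTC
>syn-snrna-005 synthetic snRNA reference (110 nt)
CAATGGCGGCACCCCAATGTGTTATAATGTGCCCTCAAAAACTGATCTCTCATTCGAAGCTGAGTTAGCC
GTTTCTATGAACTGATCTTCGAGATAGCTCCTTCGGTCGC
>syn-snrna-006 synthetic snRNA reference (110 nt)
GAGATCGGACCCTAAATAGAGATAATCCAGTGATCCGCAACCGTCTGTGGCCTAGCTACGCCCCTGCTGT
TTAGCCCTGGGGTTTGTAGGTGATCATACAATAGTCGTCG
>syn-snrna-007 synthetic snRNA reference (110 nt)
TCCTTAAACGAACACATACACGGTGTCCTGCTAAAAATTGCCCTGCGAACAACGTAATTGGGCGGGACCG
GAGTCCTCTCGCGTACCCGCGGTTGCACAAGCCGTAGGCC
>syn-snrna-008 synthetic snRNA reference (110 nt)
AAATTAGAAACCCTTGAAGTGCAGGACGATCCATGTTTTGGGAGGATTACTCTTGCTCCCTAGTGGCGCG
ACGAGCAGCATCCCCGTTCGCATACATACTCTAGTAAGTG
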