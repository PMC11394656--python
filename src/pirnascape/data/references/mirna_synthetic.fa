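>syn-mirna-001 synthetic miRNA reference (20 nt)
ATCATGTAAAGATAACTGTC
>syn-mirna-002 synthetic miRNA reference (20 nt)
ACGTTTTACGGATGAGGAAA
>syn-mirna-003 synthetic miRNA reference (20 nt)
TTGTTTCAACACAATGGAAT
>syn-mirna-004 synthetic miRNA reference (20 nt)
AACCCCAGCCCAGGGCAAGG
>syn-mirna-005 synthetic miRNA reference (20 nt)
CAGCACTCCGTAAGCGACGG
>syn-mirna-006 synthetic miRNA reference (20 nt)
AGCAGTCCACCCATTTATTG
>syn-mirna-007 synthetic miRNA reference (20 nt)
GCACGCGGTCTCCCTTCCGA
>syn-mirna-008 synthetic miRNA reference (20 nt)
TGACACCAACGGCTCCGCCC
>syn-mirna-009 synthetic miRNA reference (21 nt)
ATCGGGTTTATTGGGTTTTGT
>syn-mirna-010 synthetic miRNA reference (21 nt)
GGAAGCTGTCGATCACCAGCC
>syn-mirna-011 synthetic miRNA reference (21 nt)
TAGGCAAGGGTAAGGGTGCTA
>syn-mirna-012 synthetic miRNA reference (21 nt)
AATGCAGGACTGCGAGGAACA
>syn-mirna-013 synthetic miRNA reference (21 nt)
AACGTTCTCTGCGACTAGGAG
>syn-mirna-014 synthetic miRNA reference (21 nt)
GTTGACCGTGGCGAGATCCCG
>syn-mirna-015 synthetic miRNA reference (21 nt)
TGAAGATAAACCTAGAAGATT
>syn-mirna-016 synthetic miRNA reference (21 nt)
GGATCATCAGAGTGAACATGA
>syn-mirna-017 synthetic miRNA reference (21 nt)
CCAGGCCCTATCGAGTTGTTA
>syn-mirna-018 synthetic miRNA reference (21 nt)
TGGGTTCTAGATTTACAGCGC
>syn-mirna-019 synthetic miRNA reference (21 nt)
TGGATGACTATGCGACTCTCC
>syn-mirna-020 synthetic miRNA reference (21 nt)
CGATTCTGGTTATCAAGGTAT
>syn-mirna-021 synthetic miRNA reference (21 nt)
CGCGTTATTCGCATGCTTTCG
>syn-mirna-022 synthetic miRNA reference (21 nt)
CCAGATGAAGGTATTTAATTC
>syn-mirna-023 synthetic miRNA reference (21 nt)
GCTAAATGTAGTACTGTCGAG
>syn-mirna-024 synthetic miRNA reference (21 nt)
AGAGAGAAAACCATGGGTGGT
>syn-mirna-025 synthetic miRNA reference (22 nt)
TACCCCTGCAAGTGGAAAAACT
>syn-mirna-026 synthetic miRNA reference (22 nt)
GACACCCACTTGGCAAGTTTGT
>syn-mirna-027 synthetic miRNA reference (22 nt)
GTAGACGCCAGATGGTACCTGT
>syn-mirna-028 synthetic miRNA reference (22 nt)
ATATCCTGTGCCCCCGGGACAG
>syn-mirna-029 synthetic miRNA reference (22 nt)
GCCAGGATTTAATTGATTTAAG
>syn-mirna-030 synthetic miRNA reference (22 nt)
CTGGAGGAAACCTTTACGCAGT
>syn-mirna-031 synthetic miRNA reference (22 nt)
TGTAGACGATCCAGATCTTGTC
>syn-mirna-032 synthetic miRNA reference (22 nt)
ACAGACTATTTTAGTAGAGAAG
>syn-mirna-033 synthetic miRNA reference (22 nt)
TAACTGGTCGAGGACAGGATTG
>syn-mirna-034 synthetic miRNA reference (22 nt)
GGTAGCGTTGGAAAAGAGCGGT
>syn-mirna-035 synthetic miRNA reference (22 nt)
ATGTCTGTCCTTTACGGGGTGG
>syn-mirna-036 synthetic miRNA reference (22 nt)
GACCTCCACGGACACTCCTTTT
>syn-mirna-037 synthetic miRNA reference (22 nt)
TGTACCTTAGGACAACGCATTT
>syn-mirna-038 synthetic miRNA reference (22 nt)
TTATACAATCCGCATACTTATC
>syn-mirna-039 synthetic miRNA reference (22 nt)
CATGATGGGTCATAACGTCACG
>syn-mirna-040 synthetic miRNA reference (22 nt)
CGTTCGGGTCATCAATCCAGTC
>syn-mirna-041 synthetic miRNA reference (22 nt)
ATTGGCCATAATTCGCTGAGTC
>syn-mirna-042 synthetic miRNA reference (22 nt)
CCATTAAGGGGGAAGAACTTTC
>syn-mirna-043 synthetic miRNA reference (22 nt)
CACTTTCAGTTCGGCACATGGC
>syn-mirna-044 synthetic miRNA reference (22 nt)
ACGCCCCTTGAGGAATCCTTAC
>syn-mirna-045 synthetic miRNA reference (22 nt)
TTGACTCAACTTGCGGCTTAGA
>syn-mirna-046 synthetic miRNA reference (22 nt)
GCGTAAGCGTCGATGGTAGCGA
>syn-mirna-047 synthetic miRNA reference (22 nt)
GTCTTAGCATTTGATATTTGCG
>syn-mirna-048 synthetic miRNA reference (22 nt)
CTAGGCGGGACTTAACCGCCCC
>syn-mirna-049 synthetic miRNA reference (23 nt)
GCATTGTCTTTAGTTTACGTTAT
>syn-mirna-050 synthetic miRNA reference (23 nt)
TTATCAACGCGTCCTGATCCTAC
>syn-mirna-051 synthetic miRNA reference (23 nt)
GAGACTCCCGAATTCCCCCTGAT
>syn-mirna-052 synthetic miRNA reference (23 nt)
CCCGGTTTCACTAAGTTAAAGGC
>syn-mirna-053 synthetic miRNA reference (23 nt)
TGCAACGACTAGGAGACAATCAA
>syn-mirna-054 synthetic miRNA reference (23 nt)
GGGTTCCAAGTCTTCCTTGTCCA
>syn-mirna-055 synthetic miRNA reference (23 nt)
ATGGCAGGGAATAATCGTATCGT
>syn-mirna-056 synthetic miRNA reference (23 nt)
GTACAACCCAGAGCCTGAAAGCA
>syn-mirna-057 synthetic miRNA reference (23 nt)
GTGCCATCTTGGCAATTAGCGAA
>syn-mirna-058 synthetic miRNA reference (23 nt)
TGTGTTTGGGCAGTCACAGCAAT
>syn-mirna-059 synthetic miRNA reference (23 nt)
GCCTACCGTCGCTTACGTTATTG
>syn-mirna-060 synthetic miRNA reference (23 nt)
GTATTCCACCGACAGTGCGCCTG
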