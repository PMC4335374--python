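breakpoint: e13a2
frame_offset: 0
primers:
  forward: GGCTCTCTACGTCGTATTCACCT
  reverse: GGTGTTTGCAGCATTTGACGAGTTA
exons:
- gene: BCR
  name: BCR-e12
  ordinal: 12
  sequence: GGCTCTCTACGTCGTATTCACCTACCCATCCAACATTCCCAGGTAACGCTACGGGCACAAAGTCGCGAGTCAACAATTAGTAGAACGACGCGGAAGGATACCGTAGGCCGTGCCAGCATGCACTTTGGC
- gene: BCR
  name: BCR-e13
  ordinal: 13
  sequence: TTACGCGAAATCCTCGATAGCATACAACCGCCGATAGCCCAGCTTGCCGCCATACGAGTTGACCAGGCCAGGGGTGACATAGGGAGGTTCTTTGTAACCCCACGA
- gene: ABL1
  name: ABL1-a2
  ordinal: 2
  sequence: CCGGCCCTATCCGTTGCCAATCGCGGTTATGTACGAATACCCCGAGCTCCAGGCAGCCTTATTTCGACCCTTTTTCACGGGGCGAGGCCCATTACTCTGAGTTGTAGCTTGGAACGAACTAGGGAAAGAGTCGCGGCGCACAGGATACCAAAACCGGCGCATAGCTATTCTTCT
- gene: ABL1
  name: ABL1-a3
  ordinal: 3
  sequence: GCGCTTTTTTACAATGCAGTGCCTGCCTTCTATGGATCTCATAGCAAGCCATCGGGCGAGTACTACGAACAGTGCGCGTGGTCAGGGGCTGTTCGCATACCGTCATACGTAGTAGCTCACTCCCAAGACGATCATTGGGTTCGGCGGTCAAGGAGACGCTCAAGCCGTGTCTTCCTCAGTTCCAGA
- gene: ABL1
  name: ABL1-a4
  ordinal: 4
  sequence: TGTATAATTAATGTGTCACATCATGCCGTCCGGCTTGCTACAACGACCTGTAAGAGCGACACTGTCGGTGACTGCTTTATATTAACTGAGTTCCCGGATTGCTGTAGTCTGGCAGGGAACCGGAAACTCTTCGCAGGAACCACATTGGCCTTTGACATCGGTCAAGAGAGTGAAGCAACGAATCCGGCTCACTTTAATTCCAAGCCCCAAACCGCGGCTAACGGTGTTACATATGTTAGCTCCGTAGTCCACTGCACTGTAAGCCTCTCTGTTGATTTC
- gene: ABL1
  name: ABL1-a5
  ordinal: 5
  sequence: CCGTTAGTCGCGGGGCACAGTGAGCATAGTGAGTTTGCTTATTTTCTAGAACGTGTGGGGAACTCAAAGGGCCGGGATTTGAGCATACGAAGCAGCAGGCGTACATCGAGGCCTTACGTCGCTTCGTTTACGGTAGGCAGCGGTTGTGCCCATA
- gene: ABL1
  name: ABL1-a6
  ordinal: 6
  sequence: TTAAGTCCATATCATACGAGAGGGAGACGTGGCGAGGTTGTTGCGTCCTGGTCCCAAAGATGTCGTATGATGGCTCAGTATTAGGTCACTGGCCAACAAGTTATCACAGCGTGCACCCCGGTACCTCCTGGGACGCAAGCTGTGGAAATAGCATTAAAAACTACTTATCACTAGATCCCATTACACCCTCTG
- gene: ABL1
  name: ABL1-a7
  ordinal: 7
  sequence: GGTCAGGTGGTTACGCGGAAGATAGCACGTGTAGTGGGTCGTCGCGGGGCGAGGGCGTGCGCTCACGTCGCCTCAGCAATGAACCAAATACTAGACATAGCTACCAGATATTGACTCGCACTATGCAAC
- gene: ABL1
  name: ABL1-a8
  ordinal: 8
  sequence: TAACTCACGTCATGCCACTGCCGCTCAGCCGCGCAAGACCATCCTGCAAACCCCTGGCCAATAGTATCGAACATTGTATCGTATCGT
- gene: ABL1
  name: ABL1-a9
  ordinal: 9
  sequence: GGTACGTCTATTATATTTCTGCATATAGACCAGCATACAGGACTAACTCGTCAAATGCTGCAAACACC
codon_anchor:
  position: 654
  codon: 315
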