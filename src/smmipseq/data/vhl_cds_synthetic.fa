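>VHL_synthetic_cds synthetic stand-in VHL-like coding sequence (not the RefSeq sequence); 213 codons incl. stop
ATGGGTGTAATGCAATGCCTAGATCGATGCCAAAGACTTCGCATGCTCCCAAACGGTGGA
GTCGTTGCGCGGTGCACTATATGTACACCACGTACTAGCTACACCGAAAGATCTCTTCCG
GATTTTGAGGGGTTCAGGACTCAACCCAGTTCCAAGACTCTCAACACTGAGCGATCGATA
CTCCGAGACGTCCGCAAGGCCTCGAGTGCTTGGTTCAACGCGGTCCCCAGCCGAATCCCC
CGGGCCGTAGACCAAATCAACAAGATAAATGTCAGGACGTTTTTACGCAACTTGGCCGCC
GGTTTCGCCCCGGCTCTCCTCCTTGGAAAGAGCATAGCCAGCGCCAAGAGTCTCATAATC
AGATATCTTCCCCTACTGTGCAGCTCTCGTGAAGCTTCGGGCTGTGTCCCGGTGGGTACG
CGAGACAGTGATACTGGGAAGTCGAGGACAACACCTACACTGCGAATACTCCGAGTTGAC
ATCCCTGACCGCATACCAAGGAAACCGACAATCTTTCAAAGACATTCTATTTCGAGGAAA
ACTATGGACCAAGCTGCGAATGCTTCAGTCACGTGGGCTAGTGCTATGATTGGGCGAATC
GACCATTCCATATTGAGCACTGGACAAAGGCATCCTTGA
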