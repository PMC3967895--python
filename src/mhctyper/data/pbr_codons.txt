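# Peptide-binding-region codons of the MHC class II beta-1 domain.
# 1-based codon indices within the 90-codon exon-2 alignment, assuming the
# alignment starts at beta-chain residue 1; derived from the peptide-contact
# residues of the human class II (DR) crystal structure.  The residue-to-
# alignment mapping for any particular species is a modelling choice: edit
# this file to substitute your own mask.
9
11
13
26
28
30
32
37
38
47
56
57
60
61
65
66
67
68
70
71
72
74
76
78
81
82
85
86
88
89
90
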