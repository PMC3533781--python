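# Alleles distinguished only by polymorphism outside the peptide-binding
# sites (exons 2+3 class I, exon 2 class II) that nonetheless occur at
# significant frequencies in some populations. Nonexhaustive.
# allele<TAB>populations
A*24:02:01:02L	Pan-European/West Asian
B*07:06	Pan-European
B*44:27	Pan-European
C*04:09N	Pan-European
C*07:06	Pan-European/West Asian
C*07:18	Pan-European/Chilean
DRB1*14:54	All populations
DQB1*02:02	All populations
DQB1*03:19	Pan-European
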