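>gRNA guide RNA targeting rat SNCA exon 3 around codon 51
GTCGTTCATGGAGTGACAAC
>ssDNA_donor 80-nt single-strand donor carrying the GGA->GAT (G51D) codon edit (edited bases in lower case)
CAATTCTTTTTTTAGGTTCCAAAACTAAGGAGGGAGTCGTTCATGatGTGACAACAGGTAAGCTCTGTTGTCTTTTATCC
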