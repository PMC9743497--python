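# Trinucleotide DNase I-derived bendability parameters (Brukner et al. 1995).
# Reverse-complementary trinucleotides share a value; 32 entries expand to 64.
AAA	-0.274
AAC	-0.205
AAG	-0.081
AAT	-0.280
ACA	-0.006
ACC	-0.032
ACG	-0.033
ACT	-0.183
AGA	0.027
AGC	0.017
AGG	-0.057
ATA	0.182
ATC	-0.110
ATG	0.134
CAA	0.015
CAC	0.040
CAG	0.175
CCA	-0.246
CCC	-0.012
CCG	-0.136
CGA	-0.003
CGC	-0.077
CTA	0.090
CTC	0.031
GAA	-0.037
GAC	-0.013
GCA	0.076
GCC	0.107
GGA	0.013
GTA	0.025
TAA	0.068
TCA	0.194
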