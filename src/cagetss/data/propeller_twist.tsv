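# Dinucleotide propeller-twist angles in degrees (el Hassan & Calladine 1996).
# Reverse-complementary dinucleotides share a value; 10 entries expand to 16.
AA	-18.66
AC	-13.10
AG	-14.00
AT	-15.01
CA	-9.45
CC	-8.11
CG	-10.03
GA	-13.48
GC	-11.08
TA	-11.85
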