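# Nearest-neighbor duplex free energies, dG37 in kcal/mol (unified set,
# 1 M NaCl).  Step XY denotes 5'-XY-3' paired with its complement.  Only the
# ten unique steps are listed; the scanner resolves a step through its
# reverse complement when it is not listed directly.
# Loop penalty used for the cruciform propensity score:
#   loop(L) = loop_base + loop_slope * ln(L + 2)
# with the hairpin loop closing the spacer of the inverted repeat.
#key	value
AA	-1.00
AT	-0.88
TA	-0.58
CA	-1.45
GT	-1.44
CT	-1.28
GA	-1.30
CG	-2.17
GC	-2.24
GG	-1.98
loop_base	2.0
loop_slope	1.0
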