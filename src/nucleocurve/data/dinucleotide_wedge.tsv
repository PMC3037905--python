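# Dinucleotide wedge-model roll/tilt angles (degrees), one row per step.
# Strand-symmetric: reverse-complement steps share roll and negate tilt,
# so self-complementary steps (AT, TA, CG, GC) have tilt 0.
# Replaceable by any user table with the same 16-step layout.
step	roll_deg	tilt_deg
AA	-5.4	-0.5
AC	-2.5	-2.7
AG	1.0	-1.6
AT	-7.3	0.0
CA	6.7	0.5
CC	1.3	0.6
CG	4.6	0.0
CT	1.0	1.6
GA	9.6	2.0
GC	6.1	0.0
GG	1.3	-0.6
GT	-2.5	2.7
TA	2.8	0.0
TC	9.6	-2.0
TG	6.7	-0.5
TT	-5.4	0.5
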