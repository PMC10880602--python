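# Unified nearest-neighbor free energies, ΔG°37 in kcal/mol, per dinucleotide
# step read 5'->3' on one strand (the complementary step has the same value).
# SantaLucia PNAS 95:1460-1465 (1998), unified parameter set.
AA	-1.00
AC	-1.44
AG	-1.28
AT	-0.88
CA	-1.45
CC	-1.84
CG	-2.17
CT	-1.28
GA	-1.30
GC	-2.24
GG	-1.84
GT	-1.44
TA	-0.58
TC	-1.30
TG	-1.45
TT	-1.00
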