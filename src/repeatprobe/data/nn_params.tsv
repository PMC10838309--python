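# Unified nearest-neighbor parameters for DNA/DNA duplexes (Allawi & SantaLucia 1997).
# dinucleotide	dH_kcal_per_mol	dS_cal_per_mol_K
AA	-7.9	-22.2
TT	-7.9	-22.2
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
TG	-8.5	-22.7
GT	-8.4	-22.4
AC	-8.4	-22.4
CT	-7.8	-21.0
AG	-7.8	-21.0
GA	-8.2	-22.2
TC	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
CC	-8.0	-19.9
init_GC	0.1	-2.8
init_AT	2.3	4.1
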