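# Watson-Crick nearest-neighbor parameters, unified oligonucleotide set.
# Source: SantaLucia, PNAS 95:1460-1465 (1998). 1 M NaCl reference state.
# Stack notation: top dinucleotide 5'->3' / bottom dinucleotide 3'->5'.
# All 16 stacks listed explicitly; rotationally equivalent stacks carry
# identical values (strand-symmetry identity).
# version: unified-1998.1
stack	dH_kcal_per_mol	dS_cal_per_mol_K
AA/TT	-7.9	-22.2
TT/AA	-7.9	-22.2
AT/TA	-7.2	-20.4
TA/AT	-7.2	-21.3
CA/GT	-8.5	-22.7
TG/AC	-8.5	-22.7
GT/CA	-8.4	-22.4
AC/TG	-8.4	-22.4
CT/GA	-7.8	-21.0
AG/TC	-7.8	-21.0
GA/CT	-8.2	-22.2
TC/AG	-8.2	-22.2
CG/GC	-10.6	-27.2
GC/CG	-9.8	-24.4
GG/CC	-8.0	-19.9
CC/GG	-8.0	-19.9
init_A/T	2.3	4.1
init_G/C	0.1	-2.8
sym	0.0	-1.4
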