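# Hairpin loop initiation free energies at 37 C.
# Source: SantaLucia & Hicks, Annu Rev Biophys Biomol Struct 33:415 (2004),
# hairpin loop table.  Intermediate sizes are interpolated linearly; sizes
# beyond 30 follow the Jacobson-Stockmayer extrapolation
# dG(n) = dG(30) + 1.75 * R * T * ln(n/30).
# The penalty is treated as purely entropic (dH = 0).
# version: loops-2004.1
loop_size	dG37_kcal_per_mol
3	3.5
4	3.5
5	3.3
6	4.0
7	4.1
8	4.1
9	4.2
10	4.3
12	4.9
14	5.4
16	5.6
18	5.8
20	5.9
25	6.3
30	6.6
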