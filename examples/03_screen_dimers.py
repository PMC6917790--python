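"""Screen an oligo panel for self-dimers, cross-dimers, and hairpins.

Nearest-neighbor thermodynamics with salt correction at the step's
annealing conditions; structures are flagged with the standard reporting
thresholds (cross-dimer dG <= -9 kcal/mol, self-dimer and hairpin
dG <= -5 kcal/mol, or hairpin Tm within 3 C of the annealing
temperature).
"""

from plexscreen import Conditions, Oligo, screen_panel

panel = [
    Oligo("strong_F", "GCGCGCGCGCGCGCGC", "forward_primer", "demo"),
    Oligo("hair_F", "GGGCGCAAAAGCGCCC", "forward_primer", "demo"),
    Oligo("benign_R", "ACTGATCAGTTCAGTA", "reverse_primer", "demo"),
]
conditions = Conditions(
    step="amplification", annealing_temp=55.0,
    monovalent=50.0, divalent=1.5, dntp=0.8, oligo_conc=250.0,
)
(screen,) = screen_panel(panel, [conditions])

print("self-dimer dG (kcal/mol at 55 C):")
for name, res in screen.self_dimers.items():
    print(f"  {name}: {res.dG_at_temp:7.2f}   {res.structure}")
print("cross-dimer dG:")
for (a, b), res in screen.cross_dimers.items():
    print(f"  {a} x {b}: {res.dG_at_temp:7.2f}")
print("hairpins (dG, Tm):")
for name, res in screen.hairpins.items():
    tm = f"{res.tm:.1f} C" if res.tm is not None else "-"
    print(f"  {name}: {res.dG_at_temp:7.2f}  Tm {tm}  {res.structure}")
print(f"{len(screen.flagged)} flagged structure(s):")
for f in screen.flagged:
    partner = f" x {f.oligo2}" if f.oligo2 else ""
    print(f"  {f.kind}: {f.oligo1}{partner}  dG {f.result.dG_at_temp:.2f}  ({f.reason})")
# More negative dG = more stable artefact; flagged entries are the
# candidates to redesign before running the multiplex.
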