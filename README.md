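# plexscreen

In-silico evaluation of multiplex PCR and hybridization assays.

Highly multiplexed PCR/microarray panels fail in characteristic ways:
primers bind off-target, unintended primer combinations amplify
by-products, probes land outside their amplicon, and oligos form stable
self-dimers, cross-dimers, or hairpins that deplete the reaction.
`plexscreen` predicts all of these on user-supplied reference sequences
before any wet-lab work: it finds **every** binding site of every primer
and probe up to *k* mismatches (non-heuristically), combines oriented
hits into predicted amplicons — including cross-pair and cross-set
by-products — attaches probes, and screens the whole panel
thermodynamically.

It is aimed at people designing or debugging multiplex assays
(diagnostic panels, resistance-gene screens, microarray capture sets)
who want a deterministic, scriptable review of a primer/probe set
against their own genomes or contigs.

## The core machinery

**Search.** Each degenerate oligo is expanded over the IUPAC alphabet and
searched with an Aho-Corasick automaton built over the Hamming ball of
every variant (and its reverse complement), so one linear pass per contig
reports every placement with at most *k* mismatches (k = 0–3 per role) —
exactly, with no seeding heuristics. A vectorized sliding-window Hamming
scanner provides both an independent oracle and an automatic fallback for
pathologically large pattern sets; optional BLAST+/Bowtie adapters are
normalized to the same hit format. Hits are deduplicated so each
reference placement is reported once per parent oligo, with the
best-matching variant.

**Products.** Orientation is decided by strand: a plus-strand primer hit
extends rightward, a minus-strand hit leftward; every
rightward × leftward combination on a contig within the maximum product
size is an amplicon (start of the rightward hit through end of the
leftward hit, 1-based inclusive). Probes are attached by full containment
in the amplicon, either strand. Hits in no product are classified as
lone forward, lone reverse, or probe-without-product. A user mapping CSV
adds gene names, expected sizes (`size_match` flag), and free-form
fields.

**Thermodynamics.** Duplexes are scored with the SantaLucia unified
nearest-neighbor parameters, including the published single
internal-mismatch stacks:

    dH = Σ stacks + initiation (+ symmetry),
    dS_corr = dS + 0.368 (N−1) ln[Na+]_eq,   [Na+]_eq = mono + 120 √(Mg − dNTP)
    dG(T) = dH − T·dS_corr/1000,
    Tm = 1000·dH / (dS_corr + R ln(CT/x)) − 273.15

with x = 4 (x = 1 for self-complementary duplexes) and no concentration
term for hairpins. Self-/cross-dimers are the minimum-dG window over all
antiparallel ungapped offsets; hairpins the minimum-dG stem-loop
decomposition (stem ≥ 3 bp, loop ≥ 3 nt, tabulated loop penalties).
Structures are flagged at the conventional thresholds: cross-dimer
dG ≤ −9 kcal/mol, self-dimer and hairpin dG ≤ −5 kcal/mol, or hairpin
Tm + 3 °C ≥ the step's annealing temperature. Amplicon Tm uses the
empirical long-duplex formula `81.5 + 16.6·log10[Na+] + 0.41·%GC − 675/N`
(nearest-neighbor below 50 bp).

## Worked example

The package ships a deterministic synthetic demo assay (3 contigs,
6 primers, 2 probes, 1 degenerate primer) with planted binding sites:

```
$ plexscreen demo --out fixture
$ plexscreen run --references fixture/references.fasta \
    --primers fixture/setA.fasta --primers fixture/setB.fasta \
    --probes fixture/setA_probes.fasta --mapping fixture/mapping.csv \
    --max-mm-primer 1 --max-mm-probe 1 --out out
references: 3 contigs, 4700 bp
oligos: 8 (9 expanded variants)
raw hits: 19
hits after deduplication: 18
products: 8
unpaired hits: 4
degenerate parents summarized: 1
flagged structures: 2
```

Or from Python (`python examples/02_predict_amplicons.py`):

```
8 predicted amplicons:
  c1:101-400  300 bp  p1_F x p1_R  probes: p1_P
  c1:1001-1300  300 bp  p2_F x p2_R  probes: p1_P,p2_P
  c2:501-800  300 bp  p1_F x p1_R  probes: -
  c2:551-800  250 bp  p2_F x p1_R  probes: -
  ...
4 unpaired hits:
  p2_P @ c2:1201 -> probe_without_product
  p3_F @ c2:1301 -> forward_without_reverse
  p2_R @ c3:301 -> reverse_without_forward
  p2_F @ c3:1101 -> forward_without_reverse
```

Reading this: the two 300-bp amplicons on `c1` are the intended
products (one carries its probe, one carries two probes); `c2:551-800`
is a 250-bp **by-product** from mixing `p2_F` with `p1_R`; the unpaired
list shows a probe with no amplicon, a lone degenerate forward primer, a
lone reverse primer, and a forward primer that only binds with one
mismatch. The output directory holds `products.csv`, `unpaired.csv`,
`degenerate_summary.csv`, the dimer matrix/flags, `hairpins.csv`, a run
log, and a config echo; re-running the echoed config reproduces the
bundle byte-for-byte.

`examples/` contains one short script per capability: site search,
amplicon prediction, panel dimer/hairpin screening, and the full
pipeline.

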