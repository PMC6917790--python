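# Methods

## Scope and model

`plexscreen` treats a multiplex assay as (i) a set of primer/probe
oligos over the IUPAC alphabet, grouped into named sets, (ii) a set of
reference contigs, and (iii) two reaction steps (amplification,
hybridization), each with an annealing temperature and ion/oligo
concentrations. The pipeline predicts *where oligos bind*, *what the
bound primers would amplify*, and *which oligos form stable secondary
structures*, in that order. It deliberately models none of the reaction
kinetics: no polymerase extension, amplification efficiency, or
competition between products — a predicted amplicon means "these two
oriented binding sites exist within the size limit", nothing more.

## Search

Degenerate oligos are expanded to every concrete ACGT variant (the
Cartesian product of per-position IUPAC memberships, position-wise
lexicographic order, capped at 1024 variants per oligo so a pathological
oligo cannot blow up the pattern set).

The native backend gives the exact k-mismatch semantics by enumeration:
for each variant and each strand, every string within Hamming distance k
(k = 0–3, separately configurable for primers and probes) is inserted
into an Aho-Corasick automaton (goto/failure/output links), and each
contig is scanned once. This is exact and non-heuristic; its cost is the
Hamming-ball size Σ C(L,i)·3^i, which is why k is bounded at 3 and why a
total-pattern cap (default 5,000,000) switches the engine to the
vectorized sliding-window Hamming scanner — same hit contract, no
automaton. That scanner is also the test oracle, so the two paths are
continuously checked against each other.

Conventions chosen once and used everywhere:

* Coordinates are 1-based, inclusive, on the plus strand (BLAST subject
  convention). Minus-strand placements are found by scanning the reverse
  complement of the pattern against the plus-strand text.
* Mismatch entries read `offset:refBase>oligoBase` with the offset from
  the oligo's 5' end regardless of strand, and the reference base
  reported on the oligo's binding strand. This keeps the description
  unambiguous per oligo, which matters because downstream interpretation
  of mismatch positions (e.g. 3'-end sensitivity) is left to the user —
  no 3'-mismatch veto is applied.
* Reference characters outside ACGTN are normalized to N on load, and N
  mismatches every oligo base. When any contig contains N, the
  enumeration's substitution alphabet includes N so N-containing windows
  stay reachable and the automaton remains exactly equivalent to the
  scanner. The public mismatch-variant enumeration stays ACGT-only, with
  the analytic Σ C(L,i)·3^i count.
* Deduplication keeps one hit per (parent oligo, contig, start, strand):
  the minimal mismatch count, ties to the lowest variant index. This is
  what makes degenerate oligos report each reference placement once.

The BLAST+/Bowtie adapters are compatibility shims: they run the
external tool, discard gapped or partial-coverage alignments, rebuild
each hit from the reference (so mismatch descriptions are identical to
the native backend's), and apply the same filter and deduplication.
They are optional; the native backend never needs them, and their
parameter defaults (word size 7, 100% query coverage; seed length 20)
are exposed as configuration rather than asserted as optimal.

## Product prediction

Orientation is determined by strand alone: plus-strand primer hits
extend rightward, minus-strand hits leftward; the forward/reverse role
labels are carried for reporting only. Every rightward hit f and
leftward hit r on one contig with `f.start <= r.start` and
`r.end − f.start + 1 <= max_product_size` yields a product — all
combinations, across primer pairs and across sets (a product's set is
its forward primer's, with a `cross_set` flag). Exposing such
unintended combinations is the purpose of the tool, so nothing filters
them. No minimum product length is enforced; overlapping primer
footprints are legal products. Probes attach to every product that
fully contains them, on either strand, since a hybridization probe can
target either strand of the double-stranded amplicon.

Unpaired classification partitions the remaining hits: plus-strand
primer hits with no product → `forward_without_reverse`, minus-strand →
`reverse_without_forward`, unattached probes → `probe_without_product`.

Annotation from the mapping CSV adds gene names and free-form fields;
`size_match` is exact equality between predicted length and the expected
size of either primer (a `size_tolerance` in bp is exposed for
gel-resolution use, default 0).

## Thermodynamics

Nearest-neighbor model with the SantaLucia unified Watson-Crick
parameters (1998) and the published single internal-mismatch stacks
(Allawi & SantaLucia 1997–1998; Peyret et al. 1999), shipped as
versioned TSV files under `plexscreen/data/` and verified in the test
suite against an independent published copy. Tandem and terminal
mismatches, dangling ends, and coaxial stacking are outside the model:
duplexes must start and end on Watson-Crick pairs with isolated internal
mismatches, and callers trim terminal mismatches to the WC-anchored core
(an alignment that cannot be trimmed to such a core is reported without
thermodynamic values rather than mis-scored).

Salt enters as the entropy correction `0.368·(N−1)·ln[Na+]_eq` with the
monovalent-equivalent conversion `[Na+]_eq = mono + 120·√(max(0, Mg −
dNTP))` (all mM, dNTPs chelate divalents). A single conversion formula
was preferred over a dedicated divalent correction for determinism and
because it reproduces the expected direction of the Mg dependence.
Melting temperatures use R = 1.9872 cal/(mol·K), CT = the configured
total oligo concentration, x = 4 (x = 1 self-complementary); hairpins
are unimolecular (no concentration term). Units throughout: dH kcal/mol,
dS cal/(mol·K), dG kcal/mol, temperatures °C.

Dimers are screened exhaustively over all antiparallel ungapped offsets;
within an offset, every window that starts and ends on a WC pair and has
no adjacent mismatches is scored incrementally (cumulative stack sums),
and the global minimum-dG window at the step temperature is reported
with its alignment (mismatched columns lowercased). Windows with dG ≥ 0
collapse to an empty dG = 0 result. Hairpins enumerate all stem/loop
decompositions with stem ≥ 3 WC bp and loop ≥ 3 nt (both configurable),
score stems as NN stacks plus a tabulated, purely entropic loop penalty
(linear interpolation between tabulated sizes, Jacobson-Stockmayer
extrapolation `dG(n) = dG(30) + 1.75·R·T·ln(n/30)` beyond), and report
the minimum-dG structure *even when its dG is positive*, because the
Tm-proximity flagging rule can fire for structures that are marginally
unstable at the annealing temperature.

Flagging defaults reconcile the two reporting conventions in circulation
by exposing both as configurable thresholds: cross-dimer dG ≤ −9
kcal/mol; self-dimer dG ≤ −5; hairpin dG ≤ −5 **or** Tm + 3 °C ≥ the
step's annealing temperature ("step Tm" is read as the step's annealing
temperature). Both the matrix of all values and the flagged subset are
written, so a user applying stricter rules loses nothing.

Degenerate oligos are screened through one canonical variant: the
expansion whose perfect-match duplex has the lowest uncorrected dG37
(the strongest possible binder), ties to the lowest variant index. This
is a per-oligo property, so pair screens stay O(n²) rather than
O(n²·variants²); the variant index used is reported.

Whole-amplicon Tm uses the empirical long-duplex formula
`81.5 + 16.6·log10[Na+]_eq + 0.41·%GC − 675/N`; below 50 bp, where the
formula is not valid, the NN duplex Tm of the full product is used
instead. Products containing N report no Tm.

## Synthetic data and what the tests show

The generator produces seeded pseudorandom ACGT contigs with a chosen GC
fraction and *overwrites* (never inserts) windows with oligo sequences —
reverse-complemented for minus-strand sites, with forced mismatches
applied at stated offsets — so every expected hit, product, and unpaired
record is known a priori. The bundled demo assay (3 contigs of 2000/
1500/1200 bp, 6 primers in two sets, 2 probes, 1 degenerate primer, run
at max product size 1000 bp and k = 1) plants one topology of each kind:
intended amplicon with one probe, amplicon with two probes, two forwards
sharing a reverse, a 2×2 overlapping combination block, lone forward,
lone reverse, lone probe, and a single-mismatch site.

This emulates placement topology, not real genomes: no repeats, no
homopolymer tracts, no near-miss paralogs, no plasmid copies. Passing
the planted-recovery tests therefore demonstrates the coordinate
arithmetic, pairing, containment, classification, and deduplication
logic — not recall on real assemblies, where the same exact algorithms
simply see more windows. The search oracle tests (automaton vs
sliding-window scan, 100+ random instances, k = 0–3) are the exactness
guarantee that transfers to any input.

Problem sizes in the default test and acceptance runs (random contigs
0.5–1.5 kb, 5–12 patterns of 15–30 nt at k ≤ 1, shorter/fewer patterns
at k = 2–3; dimer brute-force cross-checks on ≤ 12-mers) were chosen to
exercise every code path while keeping a full run in the low minutes on
a single core; all are plain parameters in the tests and scale up
without code changes.

## Numerical and degenerate-input choices

* Ties in dimer/hairpin minimization break to the earliest offset/window
  in a fixed deterministic iteration order, so outputs are byte-stable.
* Zero effective ionic strength is a hard error (the salt logarithm is
  undefined), as is an empty FASTA record, a probe file with no matching
  primer set, a primer name with neither role suffix, and a duplicate
  oligo name.
* Melting temperatures are reported as undefined (empty field) when the
  Tm denominator vanishes or no structure exists.
* All CSV floats print with two decimals; rows are fully sorted; the run
  log contains no timestamps — re-running an echoed config reproduces
  the bundle byte-for-byte.

## Known limitations

* No partition function: the dimer/hairpin screen reports the single
  best ungapped structure, not an ensemble free energy; bulges and
  internal loops in dimers are not modeled.
* Tandem mismatches are unsupported by the parameter set and make a
  window end at the nearest WC anchor instead.
* The k ≤ 3 bound is intrinsic to the enumeration strategy; thermodynamic
  screening with effectively unlimited mismatches would need a different
  search engine.
* Primer/probe binding is evaluated independently per site; primer
  depletion and product competition in a real multiplex are out of
  scope.
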