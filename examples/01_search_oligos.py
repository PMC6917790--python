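"""Find every binding site of a primer on a reference, up to k mismatches.

Builds a small synthetic contig with one exact site and one single-mismatch
site planted at known positions, then searches both strands.
"""

from plexscreen import Oligo, PlantSpec, SearchConfig
from plexscreen.fixtures import generate_reference, plant_sites
from plexscreen.search import search_references, deduplicate_hits

primer = Oligo("demo_F", "ACGTTGCAGCTAGGTCAATC", "forward_primer", "demo")

reference = generate_reference(seed=1, length=600, gc=0.5, contig_id="chr_demo")
reference, truth = plant_sites(
    reference,
    [
        PlantSpec("demo_F", "chr_demo", 101, "+"),
        PlantSpec("demo_F", "chr_demo", 301, "-", forced_mismatch_offsets=(7,)),
    ],
    [primer],
)

hits = deduplicate_hits(
    search_references([primer], [reference], SearchConfig(max_mm_primer=1))
)
print(f"{len(hits)} hits for {primer.name} (<=1 mismatch):")
for h in hits:
    mm = h.mismatch_repr or "exact"
    print(f"  {h.contig_id}:{h.start}-{h.end} strand {h.strand}  "
          f"{h.mismatches} mismatch(es)  [{mm}]")
# Coordinates are 1-based plus-strand; a mismatch entry "7:G>C" means the
# reference shows G where the oligo's 7th base from its 5' end is C.
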