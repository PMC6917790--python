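"""Predict amplicons (and by-products) from primer hits, attach probes.

Uses the bundled demo assay: three contigs with planted primer pairs,
overlapping combinations, lone primers, and probes.
"""

from plexscreen import SearchConfig, demo_fixture
from plexscreen.products import attach_probes, classify_unpaired, pair_hits
from plexscreen.search import deduplicate_hits, search_references

fixture = demo_fixture(seed=42)
hits = deduplicate_hits(
    search_references(
        fixture.oligos, fixture.references,
        SearchConfig(max_mm_primer=1, max_mm_probe=1),
    )
)
primer_hits = [h for h in hits if h.role != "probe"]
probe_hits = [h for h in hits if h.role == "probe"]

products = pair_hits(
    primer_hits, fixture.max_product_size,
    {r.contig_id: r for r in fixture.references},
)
attach_probes(products, probe_hits)
unpaired = classify_unpaired(hits, products)

print(f"{len(products)} predicted amplicons:")
for p in products:
    probes = ",".join(q.oligo_name for q in p.probe_hits) or "-"
    tag = " (cross-set)" if p.cross_set else ""
    print(f"  {p.contig_id}:{p.start}-{p.end}  {p.length} bp  "
          f"{p.forward_hit.oligo_name} x {p.reverse_hit.oligo_name}"
          f"  probes: {probes}{tag}")
print(f"{len(unpaired)} unpaired hits:")
for r in unpaired:
    print(f"  {r.hit.oligo_name} @ {r.hit.contig_id}:{r.hit.start} -> {r.category}")
# Every plus-strand/minus-strand primer combination within the size limit
# is reported, including unintended pairings - those are the by-products
# a multiplex design review is looking for.
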