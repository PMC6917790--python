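"""Amplicon prediction: pair oriented primer hits, attach probes, classify
unpaired hits, summarize degenerate oligos, and annotate with the user
mapping.

Pairing is orientation-driven, not name-driven: a primer hit on the plus
strand extends rightward, one on the minus strand extends leftward, and
every rightward/leftward combination within the maximum product size is a
predicted product.  Cross-set and unintended same-pair combinations are
therefore reported deliberately — exposing by-products is the point of
the screen.  Role labels (forward/reverse) are carried through for
reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import PlexScreenError
from .oligos import MappingRecord, Oligo, ReferenceSeq, ROLE_PROBE
from .search import Hit
from .thermo import Conditions, ThermoResult, duplex_thermo, salt_correction
from .params import complement_acgt

LONG_PRODUCT_MIN_BP = 50  # below this the empirical long-duplex Tm is invalid


@dataclass(frozen=True)
class ProductAnnotation:
    """Gene mapping attached to one product."""

    gene_forward: str = ""
    gene_reverse: str = ""
    probe_genes: tuple[tuple[str, str], ...] = ()
    expected_size_forward: int | None = None
    expected_size_reverse: int | None = None
    size_match: bool | None = None
    extras: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = ()


@dataclass
class Product:
    """A predicted amplicon delimited by a rightward and a leftward hit."""

    contig_id: str
    forward_hit: Hit
    reverse_hit: Hit
    probe_hits: list[Hit] = field(default_factory=list)
    sequence: str = ""
    product_tm: float | None = None
    forward_thermo: ThermoResult | None = None
    reverse_thermo: ThermoResult | None = None
    probe_thermos: list[ThermoResult | None] = field(default_factory=list)
    annotation: ProductAnnotation | None = None

    @property
    def start(self) -> int:
        return self.forward_hit.start

    @property
    def end(self) -> int:
        return self.reverse_hit.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def set_id(self) -> str:
        return self.forward_hit.set_id

    @property
    def cross_set(self) -> bool:
        return self.forward_hit.set_id != self.reverse_hit.set_id

    def sort_key(self) -> tuple:
        return (
            self.contig_id,
            self.start,
            self.end,
            self.set_id,
            self.forward_hit.oligo_name,
            self.reverse_hit.oligo_name,
        )


CATEGORY_FORWARD_ALONE = "forward_without_reverse"
CATEGORY_REVERSE_ALONE = "reverse_without_forward"
CATEGORY_PROBE_ALONE = "probe_without_product"


@dataclass(frozen=True)
class UnpairedRecord:
    hit: Hit
    category: str


@dataclass(frozen=True)
class DegenerateSummary:
    """Aggregate of hits for one degenerate parent oligo."""

    parent_name: str
    n_variants_total: int
    n_variants_with_hits: int
    n_distinct_placements: int
    best_mismatch_count: int | None


def orient_hits(hits: list[Hit]) -> tuple[list[Hit], list[Hit]]:
    """Split primer hits into rightward- and leftward-extending lists.

    Orientation is determined by strand alone: plus-strand primer hits
    extend rightward, minus-strand hits leftward, whatever their role
    label.  Probe hits take part in neither.
    """
    rightward = [h for h in hits if h.role != ROLE_PROBE and h.strand == "+"]
    leftward = [h for h in hits if h.role != ROLE_PROBE and h.strand == "-"]
    return rightward, leftward


def pair_hits(
    hits: list[Hit],
    max_product_size: int,
    references: dict[str, ReferenceSeq] | None = None,
) -> list[Product]:
    """Emit every rightward/leftward primer-hit combination within range.

    A product requires f.start <= r.start on the same contig and a total
    span (r.end - f.start + 1) of at most ``max_product_size``.  All
    combinations are emitted, including overlapping and cross-set ones.
    When ``references`` is given, product sequences are filled in.
    """
    if max_product_size <= 0:
        raise PlexScreenError("max_product_size must be > 0")
    rightward, leftward = orient_hits(hits)
    by_contig: dict[str, tuple[list[Hit], list[Hit]]] = {}
    for h in rightward:
        by_contig.setdefault(h.contig_id, ([], []))[0].append(h)
    for h in leftward:
        by_contig.setdefault(h.contig_id, ([], []))[1].append(h)
    products: list[Product] = []
    for contig_id, (fwd, rev) in by_contig.items():
        ref = references.get(contig_id) if references else None
        for f in fwd:
            for r in rev:
                if r.start < f.start:
                    continue
                span = r.end - f.start + 1
                if span > max_product_size or span < 1:
                    continue
                seq = ref.sequence[f.start - 1 : r.end] if ref else ""
                products.append(
                    Product(
                        contig_id=contig_id,
                        forward_hit=f,
                        reverse_hit=r,
                        sequence=seq,
                    )
                )
    products.sort(key=Product.sort_key)
    return products


def attach_probes(products: list[Product], probe_hits: list[Hit]) -> list[Product]:
    """Attach each probe hit to every product that fully contains it.

    Containment is on plus-strand coordinates and either probe strand is
    accepted (a hybridization probe can target either strand of the
    double-stranded amplicon).  One probe may sit in many products and
    one product may carry many probes.
    """
    for product in products:
        for probe in probe_hits:
            if (
                probe.contig_id == product.contig_id
                and product.start <= probe.start
                and probe.end <= product.end
            ):
                product.probe_hits.append(probe)
        product.probe_hits.sort(key=Hit.sort_key)
    return products


def _hit_key(hit: Hit) -> tuple:
    return (hit.oligo_name, hit.contig_id, hit.start, hit.strand)


def classify_unpaired(hits: list[Hit], products: list[Product]) -> list[UnpairedRecord]:
    """Partition non-product hits into the three unpaired categories.

    Every primer hit in no product becomes forward_without_reverse (plus
    strand) or reverse_without_forward (minus strand); every probe hit
    attached to no product becomes probe_without_product.
    """
    in_products: set[tuple] = set()
    for product in products:
        in_products.add(_hit_key(product.forward_hit))
        in_products.add(_hit_key(product.reverse_hit))
        for probe in product.probe_hits:
            in_products.add(_hit_key(probe))
    records: list[UnpairedRecord] = []
    for hit in hits:
        if _hit_key(hit) in in_products:
            continue
        if hit.role == ROLE_PROBE:
            category = CATEGORY_PROBE_ALONE
        elif hit.strand == "+":
            category = CATEGORY_FORWARD_ALONE
        else:
            category = CATEGORY_REVERSE_ALONE
        records.append(UnpairedRecord(hit, category))
    records.sort(key=lambda r: r.hit.sort_key())
    return records


def summarize_degenerate(
    oligos: list[Oligo], hits: list[Hit]
) -> list[DegenerateSummary]:
    """One aggregate row per degenerate parent oligo (deduplicated hits in).

    Non-degenerate oligos are omitted; a degenerate parent with zero hits
    still gets a row.
    """
    by_parent: dict[str, list[Hit]] = {}
    for hit in hits:
        by_parent.setdefault(hit.oligo_name, []).append(hit)
    rows: list[DegenerateSummary] = []
    for oligo in oligos:
        if not oligo.is_degenerate:
            continue
        parent_hits = by_parent.get(oligo.name, [])
        placements = {(h.contig_id, h.start, h.strand) for h in parent_hits}
        rows.append(
            DegenerateSummary(
                parent_name=oligo.name,
                n_variants_total=oligo.degeneracy,
                n_variants_with_hits=len({h.variant_index for h in parent_hits}),
                n_distinct_placements=len(placements),
                best_mismatch_count=(
                    min(h.mismatches for h in parent_hits) if parent_hits else None
                ),
            )
        )
    rows.sort(key=lambda r: r.parent_name)
    return rows


def annotate_products(
    products: list[Product],
    mapping: list[MappingRecord],
    *,
    size_tolerance: int = 0,
) -> list[Product]:
    """Attach gene names, extra fields, and the size_match flag.

    ``size_match`` is True iff an expected product size exists for either
    primer and matches the predicted length within ``size_tolerance`` bp
    (exact by default); None when neither primer has an expectation.
    Oligos absent from the mapping simply get empty fields.
    """
    by_name = {m.oligo_name: m for m in mapping}
    for product in products:
        fwd = by_name.get(product.forward_hit.oligo_name)
        rev = by_name.get(product.reverse_hit.oligo_name)
        probe_genes = []
        extras: list[tuple[str, tuple]] = []
        for record, name in (
            (fwd, product.forward_hit.oligo_name),
            (rev, product.reverse_hit.oligo_name),
        ):
            if record and record.extra_fields:
                extras.append((name, record.extra_fields))
        for probe in product.probe_hits:
            rec = by_name.get(probe.oligo_name)
            probe_genes.append((probe.oligo_name, rec.gene_name if rec else ""))
            if rec and rec.extra_fields:
                extras.append((probe.oligo_name, rec.extra_fields))
        expectations = [
            rec.expected_product_size
            for rec in (fwd, rev)
            if rec and rec.expected_product_size is not None
        ]
        if expectations:
            size_match: bool | None = any(
                abs(product.length - e) <= size_tolerance for e in expectations
            )
        else:
            size_match = None
        product.annotation = ProductAnnotation(
            gene_forward=fwd.gene_name if fwd else "",
            gene_reverse=rev.gene_name if rev else "",
            probe_genes=tuple(probe_genes),
            expected_size_forward=fwd.expected_product_size if fwd else None,
            expected_size_reverse=rev.expected_product_size if rev else None,
            size_match=size_match,
            extras=tuple(extras),
        )
    return products


def product_tm(sequence: str, conditions: Conditions) -> float | None:
    """Melting temperature of a whole amplicon.

    For products of >= 50 bp the empirical long-duplex formula

        Tm = 81.5 + 16.6*log10([Na+]_eq M) + 0.41*%GC - 675/N

    is used with the monovalent-equivalent salt; shorter products fall
    back to the nearest-neighbor duplex Tm.  Returns None when the
    sequence contains N.
    """
    if not sequence:
        raise PlexScreenError("cannot compute Tm of an empty product")
    if any(c not in "ACGT" for c in sequence):
        return None
    na_eq = salt_correction(conditions.monovalent, conditions.divalent, conditions.dntp)
    n = len(sequence)
    if n < LONG_PRODUCT_MIN_BP:
        return duplex_thermo(sequence, complement_acgt(sequence), conditions).tm
    gc_pct = 100.0 * sum(1 for c in sequence if c in "GC") / n
    return (
        81.5
        + 16.6 * math.log10(na_eq / 1000.0)
        + 0.41 * gc_pct
        - 675.0 / n
    )
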