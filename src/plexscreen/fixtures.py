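"""Deterministic synthetic test data: random reference contigs with
planted primer/probe binding sites and the ground-truth records the
planted design implies.

Planting overwrites a window of the reference with the oligo sequence
(reverse-complemented for minus-strand sites), optionally mutating stated
offsets to force mismatches, so every expected hit coordinate is known a
priori.  The bundled demo fixture covers the canonical assay topologies:
lone forward / lone reverse primers, multiple forwards sharing one
reverse, overlapping amplicon combinations, a probe inside an amplicon,
two probes inside one amplicon, a probe with no product, and one
degenerate primer.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import PlexScreenError
from .oligos import (
    ROLE_FORWARD,
    ROLE_PROBE,
    ROLE_REVERSE,
    MappingRecord,
    Oligo,
    ReferenceSeq,
    expand_degenerate,
    reverse_complement,
    write_fasta,
)
from .search import Hit

_MUTATE_NEXT = {"A": "C", "C": "G", "G": "T", "T": "A"}
_COMPL = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class PlantSpec:
    """One planted oligo binding site."""

    oligo_name: str
    contig_id: str
    position: int  # 1-based plus-strand start of the planted window
    strand: str  # '+' or '-'
    forced_mismatch_offsets: tuple[int, ...] = ()  # 1-based from oligo 5' end
    variant_index: int = 0  # which expansion of a degenerate parent to plant
    allow_overlap: bool = False
    note: str = ""


def generate_reference(
    seed: int, length: int, gc: float = 0.5, contig_id: str = "contig"
) -> ReferenceSeq:
    """Reproducible pseudorandom ACGT contig with expected GC fraction."""
    if length <= 0:
        raise PlexScreenError("reference length must be > 0")
    if not (0.0 <= gc <= 1.0):
        raise PlexScreenError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    return ReferenceSeq(contig_id, "".join(bases), source_file="<synthetic>")


def plant_sites(
    reference: ReferenceSeq,
    specs: list[PlantSpec],
    oligos: list[Oligo],
) -> tuple[ReferenceSeq, list[Hit]]:
    """Overwrite reference windows with oligo sequences; return truth hits.

    Each spec yields exactly one expected :class:`Hit` whose mismatch
    count equals the number of forced mismatches.  Overlapping windows
    are an error unless a spec opts in with ``allow_overlap``.
    """
    by_name = {o.name: o for o in oligos}
    seq = list(reference.sequence)
    occupied: list[tuple[int, int, bool]] = []
    truth: list[Hit] = []
    for spec in specs:
        oligo = by_name.get(spec.oligo_name)
        if oligo is None:
            raise PlexScreenError(f"unknown oligo '{spec.oligo_name}' in plant spec")
        variant = expand_degenerate(oligo)[spec.variant_index].sequence
        length = len(variant)
        start0 = spec.position - 1
        end0 = start0 + length - 1
        if start0 < 0 or end0 >= len(seq):
            raise PlexScreenError(
                f"planted window for {spec.oligo_name} at {spec.position} "
                f"exceeds contig bounds"
            )
        for s, e, ok in occupied:
            if start0 <= e and s <= end0 and not (ok and spec.allow_overlap):
                raise PlexScreenError(
                    f"planted window for {spec.oligo_name} at {spec.position} "
                    "overlaps an earlier site (set allow_overlap to permit)"
                )
        occupied.append((start0, end0, spec.allow_overlap))
        window = list(variant if spec.strand == "+" else reverse_complement(variant))
        entries = []
        for offset in spec.forced_mismatch_offsets:
            if not (1 <= offset <= length):
                raise PlexScreenError(
                    f"forced mismatch offset {offset} outside oligo length {length}"
                )
            j = offset - 1 if spec.strand == "+" else length - offset
            window[j] = _MUTATE_NEXT[window[j]]
            ref_base = window[j] if spec.strand == "+" else _COMPL[window[j]]
            entries.append((offset, ref_base, variant[offset - 1]))
        seq[start0 : end0 + 1] = window
        entries.sort()
        truth.append(
            Hit(
                oligo_name=oligo.name,
                set_id=oligo.set_id,
                role=oligo.role,
                variant_index=spec.variant_index,
                contig_id=reference.contig_id,
                strand=spec.strand,
                start=spec.position,
                end=spec.position + length - 1,
                mismatches=len(entries),
                mismatch_repr=";".join(f"{o}:{r}>{q}" for o, r, q in entries),
                matched_ref_seq="".join(window),
            )
        )
    return (
        ReferenceSeq(reference.contig_id, "".join(seq), reference.source_file),
        truth,
    )


# ---------------------------------------------------------------------------
# bundled demo fixture


@dataclass
class DemoFixture:
    """Synthetic three-contig assay with hand-derived ground truth."""

    references: list[ReferenceSeq]
    oligos: list[Oligo]
    mapping: list[MappingRecord]
    truth_hits: list[Hit]
    # (contig, start, end, length, fwd, rev, probe names)
    truth_products: list[tuple[str, int, int, int, str, str, tuple[str, ...]]]
    # (oligo, contig, start, strand, category)
    truth_unpaired: list[tuple[str, str, int, str, str]]
    # (parent, n_variants_total, n_variants_with_hits, n_placements, best_mm)
    truth_degenerate: list[tuple[str, int, int, int, int]]
    max_product_size: int = 1000
    max_mm_primer: int = 1
    max_mm_probe: int = 1
    primer_files: dict[str, list[str]] = field(default_factory=dict)
    probe_files: dict[str, list[str]] = field(default_factory=dict)


_DEMO_PRIMERS = {
    "p1_F": ("ACGTTGCAGCTAGGTCAATC", ROLE_FORWARD, "setA"),
    "p1_R": ("TGCAACGGTCCATAGGCTTA", ROLE_REVERSE, "setA"),
    "p2_F": ("GATCCGTAACGGTTACGTGA", ROLE_FORWARD, "setA"),
    "p2_R": ("CCTAGGATCCGTTAACGCAT", ROLE_REVERSE, "setA"),
    "p3_F": ("ACRGTTCAGGCTAACGTTGC", ROLE_FORWARD, "setB"),
    "p3_R": ("TTGACGCATCCGGATCAATG", ROLE_REVERSE, "setB"),
}
_DEMO_PROBES = {
    "p1_P": ("TGGCATCCGTTAGGCACT", "setA"),
    "p2_P": ("CCATTAGGCGATCCGTTA", "setA"),
}


def demo_fixture(seed: int = 42) -> DemoFixture:
    """Build the bundled demo assay (3 contigs, 6 primers, 2 probes).

    Planted design (run with max product size 1000, one mismatch allowed):

    * c1: amplicon p1_F[101]..p1_R[381-400] (300 bp) carrying probe p1_P;
      amplicon p2_F[1001]..p2_R[1281-1300] (300 bp) carrying both probes.
    * c2: two forwards (p1_F[501], p2_F[551]) sharing one reverse
      p1_R[781-800] -> two overlapping amplicons; lone forward p3_F[1301]
      (the degenerate primer, planted as variant 0); probe p2_P[1201]
      inside no amplicon.
    * c3: two forwards x two reverses (p1_F[601,621] x p1_R[841,881]) ->
      four amplicon combinations; lone reverse p2_R[301]; lone forward
      p2_F[1101] planted with one forced mismatch at offset 5.
    """
    oligos = [
        Oligo(name, seq, role, set_id)
        for name, (seq, role, set_id) in _DEMO_PRIMERS.items()
    ] + [Oligo(name, seq, ROLE_PROBE, set_id) for name, (seq, set_id) in _DEMO_PROBES.items()]

    plan = {
        "c1": (2000, [
            PlantSpec("p1_F", "c1", 101, "+"),
            PlantSpec("p1_P", "c1", 181, "+"),
            PlantSpec("p1_R", "c1", 381, "-"),
            PlantSpec("p2_F", "c1", 1001, "+"),
            PlantSpec("p1_P", "c1", 1041, "+"),
            PlantSpec("p2_P", "c1", 1121, "+"),
            PlantSpec("p2_R", "c1", 1281, "-"),
        ]),
        "c2": (1500, [
            PlantSpec("p1_F", "c2", 501, "+"),
            PlantSpec("p2_F", "c2", 551, "+"),
            PlantSpec("p1_R", "c2", 781, "-"),
            PlantSpec("p2_P", "c2", 1201, "+"),
            PlantSpec("p3_F", "c2", 1301, "+", variant_index=0),
        ]),
        "c3": (1200, [
            PlantSpec("p2_R", "c3", 301, "-"),
            PlantSpec("p1_F", "c3", 601, "+"),
            PlantSpec("p1_F", "c3", 621, "+"),
            PlantSpec("p1_R", "c3", 841, "-"),
            PlantSpec("p1_R", "c3", 881, "-"),
            PlantSpec("p2_F", "c3", 1101, "+", forced_mismatch_offsets=(5,)),
        ]),
    }
    references: list[ReferenceSeq] = []
    truth_hits: list[Hit] = []
    for i, (contig_id, (length, specs)) in enumerate(plan.items()):
        ref = generate_reference(seed + i, length, 0.5, contig_id)
        ref, hits = plant_sites(ref, specs, oligos)
        references.append(ref)
        truth_hits.extend(hits)
    truth_hits.sort(key=Hit.sort_key)

    truth_products = [
        ("c1", 101, 400, 300, "p1_F", "p1_R", ("p1_P",)),
        ("c1", 1001, 1300, 300, "p2_F", "p2_R", ("p1_P", "p2_P")),
        ("c2", 501, 800, 300, "p1_F", "p1_R", ()),
        ("c2", 551, 800, 250, "p2_F", "p1_R", ()),
        ("c3", 601, 860, 260, "p1_F", "p1_R", ()),
        ("c3", 601, 900, 300, "p1_F", "p1_R", ()),
        ("c3", 621, 860, 240, "p1_F", "p1_R", ()),
        ("c3", 621, 900, 280, "p1_F", "p1_R", ()),
    ]
    truth_unpaired = [
        ("p3_F", "c2", 1301, "+", "forward_without_reverse"),
        ("p2_P", "c2", 1201, "+", "probe_without_product"),
        ("p2_R", "c3", 301, "-", "reverse_without_forward"),
        ("p2_F", "c3", 1101, "+", "forward_without_reverse"),
    ]
    # p3_F (AC[R]GTT...): variant 0 planted exactly; variant 1 matches the
    # same window with 1 mismatch at k=1 and is collapsed by dedup.
    truth_degenerate = [("p3_F", 2, 1, 1, 0)]

    mapping = [
        MappingRecord("p1_F", "blaTEM", 300, (("info", "beta-lactamase"),)),
        MappingRecord("p1_R", "blaTEM", 300, (("info", "beta-lactamase"),)),
        MappingRecord("p2_F", "vanA", 300, (("info", "glycopeptide"),)),
        MappingRecord("p2_R", "vanA", 300, (("info", "glycopeptide"),)),
        MappingRecord("p3_F", "mecA", None, (("info", "methicillin"),)),
        MappingRecord("p3_R", "mecA", None, (("info", "methicillin"),)),
        MappingRecord("p1_P", "blaTEM", None, (("info", "probe"),)),
        MappingRecord("p2_P", "vanA", None, (("info", "probe"),)),
    ]

    primer_files = {
        "setA": ["p1_F", "p1_R", "p2_F", "p2_R"],
        "setB": ["p3_F", "p3_R"],
    }
    probe_files = {"setA": ["p1_P", "p2_P"]}
    return DemoFixture(
        references=references,
        oligos=oligos,
        mapping=mapping,
        truth_hits=truth_hits,
        truth_products=truth_products,
        truth_unpaired=truth_unpaired,
        truth_degenerate=truth_degenerate,
        primer_files=primer_files,
        probe_files=probe_files,
    )


def write_demo_fixture(out_dir: str | os.PathLike, seed: int = 42) -> DemoFixture:
    """Write the demo fixture as FASTA/CSV files under ``out_dir``.

    Produces ``references.fasta``, one primer FASTA per set, matching
    ``*_probes.fasta`` files, ``mapping.csv``, and ``truth_hits.csv``.
    """
    fixture = demo_fixture(seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(
        os.path.join(out_dir, "references.fasta"),
        [(r.contig_id, r.sequence) for r in fixture.references],
    )
    by_name = {o.name: o for o in fixture.oligos}
    for set_id, names in fixture.primer_files.items():
        write_fasta(
            os.path.join(out_dir, f"{set_id}.fasta"),
            [(n, by_name[n].sequence) for n in names],
        )
    for set_id, names in fixture.probe_files.items():
        write_fasta(
            os.path.join(out_dir, f"{set_id}_probes.fasta"),
            [(n, by_name[n].sequence) for n in names],
        )
    with open(os.path.join(out_dir, "mapping.csv"), "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["oligo", "gene", "expected_size", "info"])
        for rec in fixture.mapping:
            writer.writerow([
                rec.oligo_name,
                rec.gene_name,
                rec.expected_product_size if rec.expected_product_size else "",
                dict(rec.extra_fields).get("info", ""),
            ])
    with open(os.path.join(out_dir, "truth_hits.csv"), "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["oligo_name", "contig_id", "strand", "start", "end", "mismatches"]
        )
        for h in fixture.truth_hits:
            writer.writerow(
                [h.oligo_name, h.contig_id, h.strand, h.start, h.end, h.mismatches]
            )
    return fixture
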