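"""Oligo and reference I/O: FASTA parsing, primer/probe set conventions,
IUPAC degeneracy expansion, and the gene-mapping CSV.

Conventions
-----------
* A primer FASTA file defines one multiplex *set*; the set id is the file
  basename without extension.
* Probes for set ``X`` live in a file whose basename is ``X_probes``
  (suffix configurable).
* Primer roles are inferred from name suffixes, ``_F`` for forward and
  ``_R`` for reverse by default.
* Reference sequences are uppercased and any character outside ``ACGTN``
  is normalized to ``N`` (it then mismatches every oligo base).
"""

from __future__ import annotations

import csv
import itertools
import logging
import os
import re
from dataclasses import dataclass, field

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import InputFormatError

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes -> the set of concrete bases each stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

ROLE_FORWARD = "forward_primer"
ROLE_REVERSE = "reverse_primer"
ROLE_PROBE = "probe"

DEFAULT_EXPANSION_CAP = 1024


@dataclass(frozen=True)
class Oligo:
    """A named primer or probe sequence (5'->3') over the IUPAC alphabet."""

    name: str
    sequence: str
    role: str
    set_id: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputFormatError(f"oligo '{self.name}' has an empty sequence")
        bad = [c for c in self.sequence if c not in IUPAC_CODES]
        if bad:
            raise InputFormatError(
                f"oligo '{self.name}' contains invalid character(s) {bad!r}"
            )
        if self.role not in (ROLE_FORWARD, ROLE_REVERSE, ROLE_PROBE):
            raise InputFormatError(f"oligo '{self.name}': unknown role {self.role!r}")

    @property
    def is_degenerate(self) -> bool:
        return any(c not in "ACGT" for c in self.sequence)

    @property
    def degeneracy(self) -> int:
        """Analytic expansion count: product of per-position code sizes."""
        n = 1
        for c in self.sequence:
            n *= len(IUPAC_CODES[c])
        return n


@dataclass(frozen=True)
class ExpandedOligo:
    """One concrete ACGT member of a (possibly degenerate) parent oligo."""

    parent_name: str
    variant_index: int
    sequence: str


@dataclass(frozen=True)
class ReferenceSeq:
    """One reference contig; sequence over ACGTN, plus-strand."""

    contig_id: str
    sequence: str
    source_file: str = ""


@dataclass(frozen=True)
class MappingRecord:
    """One row of the user mapping CSV: oligo -> gene/expected size/extras."""

    oligo_name: str
    gene_name: str
    expected_product_size: int | None
    extra_fields: tuple[tuple[str, str], ...] = ()


def parse_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(header, sequence)`` records.

    Sequences are uppercased with line breaks joined; record order is
    preserved.  Raises :class:`InputFormatError` for a missing file, an
    empty file, or an empty sequence under a header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputFormatError(f"FASTA file not found: {path}")
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            seq = seq.upper().replace(" ", "")
            if not seq:
                raise InputFormatError(f"empty sequence for '{header}' in {path}")
            records.append((header, seq))
    if not records:
        raise InputFormatError(f"no FASTA records found in {path}")
    return records


def load_references(paths: list[str | os.PathLike]) -> list[ReferenceSeq]:
    """Load reference contigs from one or more multi-FASTA files.

    The contig id is the first whitespace-delimited token of the header.
    Characters outside ACGTN are normalized to N (logged).
    """
    refs: list[ReferenceSeq] = []
    seen: set[str] = set()
    for path in paths:
        for header, seq in parse_fasta(path):
            contig_id = header.split()[0]
            if contig_id in seen:
                raise InputFormatError(f"duplicate contig id '{contig_id}'")
            seen.add(contig_id)
            cleaned = re.sub("[^ACGTN]", "N", seq)
            n_fixed = sum(1 for a, b in zip(seq, cleaned) if a != b)
            if n_fixed:
                logger.warning(
                    "contig %s: normalized %d non-ACGTN character(s) to N",
                    contig_id, n_fixed,
                )
            refs.append(ReferenceSeq(contig_id, cleaned, os.fspath(path)))
    return refs


def _basename_noext(path: str | os.PathLike) -> str:
    return os.path.splitext(os.path.basename(os.fspath(path)))[0]


def load_oligo_sets(
    primer_paths: list[str | os.PathLike],
    probe_paths: list[str | os.PathLike] | None = None,
    *,
    forward_suffix: str = "_F",
    reverse_suffix: str = "_R",
    probe_file_suffix: str = "_probes",
) -> list[Oligo]:
    """Load primer sets and their matching probe sets.

    Each primer file defines one set (set id = basename without extension).
    A probe file must be named ``<set>_probes.<ext>`` for some primer file
    ``<set>.<ext>``; its oligos join that set with role ``probe``.  Primer
    roles come from the name suffix (``_F``/``_R`` by default).  Oligo names
    must be globally unique.
    """
    probe_paths = probe_paths or []
    set_ids = {_basename_noext(p): p for p in primer_paths}
    oligos: list[Oligo] = []
    names: set[str] = set()

    def _add(oligo: Oligo) -> None:
        if oligo.name in names:
            raise InputFormatError(f"duplicate oligo name '{oligo.name}'")
        names.add(oligo.name)
        oligos.append(oligo)

    for path in primer_paths:
        set_id = _basename_noext(path)
        for header, seq in parse_fasta(path):
            name = header.split()[0]
            if name.endswith(forward_suffix):
                role = ROLE_FORWARD
            elif name.endswith(reverse_suffix):
                role = ROLE_REVERSE
            else:
                raise InputFormatError(
                    f"cannot infer role for primer '{name}' in {path}: name must "
                    f"end in '{forward_suffix}' or '{reverse_suffix}'"
                )
            _add(Oligo(name, seq, role, set_id))

    for path in probe_paths:
        base = _basename_noext(path)
        if not base.endswith(probe_file_suffix):
            raise InputFormatError(
                f"probe file {path} does not end in '{probe_file_suffix}'"
            )
        set_id = base[: -len(probe_file_suffix)]
        if set_id not in set_ids:
            raise InputFormatError(
                f"probe file {path} has no matching primer file '{set_id}'"
            )
        for header, seq in parse_fasta(path):
            name = header.split()[0]
            _add(Oligo(name, seq, ROLE_PROBE, set_id))

    return oligos


def expand_degenerate(
    oligo: Oligo, *, cap: int = DEFAULT_EXPANSION_CAP
) -> list[ExpandedOligo]:
    """Enumerate every concrete ACGT sequence denoted by a degenerate oligo.

    Variants are ordered position-wise lexicographically (the Cartesian
    product of per-position expansions in table order); a non-degenerate
    oligo yields itself as variant 0.  Exceeding ``cap`` variants is fatal.
    """
    count = oligo.degeneracy
    if count > cap:
        raise InputFormatError(
            f"oligo '{oligo.name}' expands to {count} variants "
            f"(cap {cap}); too degenerate to enumerate"
        )
    choices = [IUPAC_CODES[c] for c in oligo.sequence]
    return [
        ExpandedOligo(oligo.name, i, "".join(combo))
        for i, combo in enumerate(itertools.product(*choices))
    ]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (involution on all 15 codes)."""
    out = []
    for i, c in enumerate(reversed(seq)):
        comp = IUPAC_COMPLEMENT.get(c)
        if comp is None:
            pos = len(seq) - i  # 1-based position in the input orientation
            raise InputFormatError(
                f"invalid nucleotide {c!r} at position {pos} in {seq!r}"
            )
        out.append(comp)
    return "".join(out)


def load_mapping_csv(path: str | os.PathLike) -> list[MappingRecord]:
    """Load the oligo -> gene mapping CSV.

    Header row required.  Columns: oligo name, gene name, expected product
    size (optional), then any number of free-form information fields that
    are carried verbatim into the output reports.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputFormatError(f"mapping file not found: {path}")
    records: list[MappingRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise InputFormatError(f"mapping file {path} is empty") from None
        if len(header) < 3:
            raise InputFormatError(
                f"mapping file {path}: need at least 3 columns "
                "(oligo, gene, expected size)"
            )
        extra_names = header[3:]
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            row = row + [""] * (len(header) - len(row))
            oligo_name, gene_name, size_cell = (c.strip() for c in row[:3])
            if not oligo_name:
                raise InputFormatError(f"{path} row {rownum}: empty oligo name")
            if oligo_name in seen:
                raise InputFormatError(
                    f"{path} row {rownum}: duplicate oligo '{oligo_name}'"
                )
            seen.add(oligo_name)
            if size_cell == "":
                size: int | None = None
            else:
                try:
                    size = int(size_cell)
                except ValueError:
                    raise InputFormatError(
                        f"{path} row {rownum}: expected product size "
                        f"{size_cell!r} is not an integer"
                    ) from None
                if size <= 0:
                    raise InputFormatError(
                        f"{path} row {rownum}: expected product size must be > 0"
                    )
            extras = tuple(zip(extra_names, (c for c in row[3 : 3 + len(extra_names)])))
            records.append(MappingRecord(oligo_name, gene_name, size, extras))
    return records


def write_fasta(path: str | os.PathLike, records: list[tuple[str, str]]) -> None:
    """Write ``(header, sequence)`` records as FASTA, 70 columns per line."""
    with open(path, "w") as handle:
        for header, seq in records:
            handle.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
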