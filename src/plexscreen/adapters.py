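"""Optional external search backends (BLAST+, Bowtie 1), normalized to the
native Hit contract.

These are best-effort compatibility shims: they invoke the external tool,
parse its native tabular output, keep only ungapped full-length
alignments, recompute mismatch descriptions from the reference (so N
handling and strand conventions match the native backend exactly), and
apply the same mismatch filter and deduplication.  The native
Aho-Corasick backend never requires them.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile

from .errors import ExternalToolError
from .oligos import Oligo, ReferenceSeq, expand_degenerate, reverse_complement, write_fasta
from .search import (
    METHOD_BLAST,
    METHOD_BOWTIE,
    Hit,
    SearchConfig,
    _mismatch_repr,
    deduplicate_hits,
)


def _require(binary: str) -> str:
    path = shutil.which(binary)
    if path is None:
        raise ExternalToolError(f"{binary} not found on PATH")
    return path


def _run(cmd: list[str], **kwargs) -> subprocess.CompletedProcess:
    proc = subprocess.run(cmd, capture_output=True, text=True, **kwargs)
    if proc.returncode != 0:
        raise ExternalToolError(
            f"{cmd[0]} exited with status {proc.returncode}: {proc.stderr.strip()}"
        )
    return proc


def _hit_from_placement(
    oligo: Oligo,
    variant_index: int,
    variant_seq: str,
    ref: ReferenceSeq,
    strand: str,
    start: int,
) -> Hit | None:
    """Rebuild a Hit from a reported placement, recomputing mismatches."""
    length = len(variant_seq)
    end = start + length - 1
    if start < 1 or end > len(ref.sequence):
        return None
    window = ref.sequence[start - 1 : end]
    oriented = variant_seq if strand == "+" else reverse_complement(variant_seq)
    repr_ = _mismatch_repr(window, oriented, strand)
    return Hit(
        oligo_name=oligo.name,
        set_id=oligo.set_id,
        role=oligo.role,
        variant_index=variant_index,
        contig_id=ref.contig_id,
        strand=strand,
        start=start,
        end=end,
        mismatches=repr_.count(":"),
        mismatch_repr=repr_,
        matched_ref_seq=window,
    )


def run_external_adapter(
    method: str,
    oligos: list[Oligo],
    references: list[ReferenceSeq],
    config: SearchConfig,
) -> list[Hit]:
    """Search with an external tool, returning native-format hits.

    Requires the tool's executables on PATH; gapped or partial-coverage
    alignments are discarded, and the role-specific mismatch filter plus
    deduplication are applied exactly as in the native backend.
    """
    if method == METHOD_BLAST:
        hits = _blast_search(oligos, references, config)
    elif method == METHOD_BOWTIE:
        hits = _bowtie_search(oligos, references, config)
    else:
        raise ExternalToolError(f"unknown external method {method!r}")
    hits = [
        h for h in hits if h.mismatches <= config.max_mismatches(h.role)
    ]
    return deduplicate_hits(hits)


def _expanded_queries(oligos: list[Oligo]):
    queries = []
    for oligo in oligos:
        for variant in expand_degenerate(oligo):
            queries.append((oligo, variant.variant_index, variant.sequence))
    return queries


def _blast_search(
    oligos: list[Oligo], references: list[ReferenceSeq], config: SearchConfig
) -> list[Hit]:
    blastn = _require("blastn")
    makeblastdb = _require("makeblastdb")
    refs_by_id = {r.contig_id: r for r in references}
    queries = _expanded_queries(oligos)
    hits: list[Hit] = []
    with tempfile.TemporaryDirectory(prefix="plexscreen_blast_") as tmp:
        db_fasta = os.path.join(tmp, "refs.fasta")
        write_fasta(db_fasta, [(r.contig_id, r.sequence) for r in references])
        _run([makeblastdb, "-in", db_fasta, "-dbtype", "nucl"])
        query_fasta = os.path.join(tmp, "queries.fasta")
        write_fasta(query_fasta, [(f"q{i}", seq) for i, (_, _, seq) in enumerate(queries)])
        proc = _run([
            blastn, "-task", "blastn-short",
            "-db", db_fasta, "-query", query_fasta,
            "-outfmt", "6 qseqid sseqid length mismatch gapopen qstart qend sstart send",
            "-evalue", "1000",
            "-word_size", str(config.blast_word_size),
            "-qcov_hsp_perc", str(config.blast_qcov_hsp_perc),
            "-dust", "no", "-soft_masking", "false",
            "-max_target_seqs", "1000",
            "-num_threads", "1",
        ])
        for line in proc.stdout.splitlines():
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            qseqid, sseqid = fields[0], fields[1]
            length, _mm, gapopen = int(fields[2]), int(fields[3]), int(fields[4])
            qstart, qend = int(fields[5]), int(fields[6])
            sstart, send = int(fields[7]), int(fields[8])
            oligo, variant_index, seq = queries[int(qseqid[1:])]
            # full-coverage, ungapped alignments only
            if gapopen or length != len(seq) or qstart != 1 or qend != len(seq):
                continue
            if sstart <= send:
                strand, start = "+", sstart
            else:
                strand, start = "-", send
            hit = _hit_from_placement(
                oligo, variant_index, seq, refs_by_id[sseqid], strand, start
            )
            if hit is not None:
                hits.append(hit)
    return hits


def _bowtie_search(
    oligos: list[Oligo], references: list[ReferenceSeq], config: SearchConfig
) -> list[Hit]:
    bowtie = _require("bowtie")
    bowtie_build = _require("bowtie-build")
    refs_by_id = {r.contig_id: r for r in references}
    queries = _expanded_queries(oligos)
    k = max(config.max_mm_primer, config.max_mm_probe)
    hits: list[Hit] = []
    with tempfile.TemporaryDirectory(prefix="plexscreen_bowtie_") as tmp:
        ref_fasta = os.path.join(tmp, "refs.fasta")
        write_fasta(ref_fasta, [(r.contig_id, r.sequence) for r in references])
        index = os.path.join(tmp, "index")
        _run([bowtie_build, "--quiet", ref_fasta, index])
        query_fasta = os.path.join(tmp, "queries.fasta")
        write_fasta(query_fasta, [(f"q{i}", seq) for i, (_, _, seq) in enumerate(queries)])
        proc = _run([
            bowtie, "-f", "--all", "-v", str(min(k, 3)),
            "--seedlen", str(config.bowtie_seedlen),
            "--maqerr", str(config.bowtie_maqerr),
            "--quiet", index, query_fasta,
        ])
        for line in proc.stdout.splitlines():
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            qname, strand, contig_id, offset = fields[0], fields[1], fields[2], fields[3]
            oligo, variant_index, seq = queries[int(qname[1:])]
            hit = _hit_from_placement(
                oligo, variant_index, seq, refs_by_id[contig_id], strand,
                int(offset) + 1,
            )
            if hit is not None:
                hits.append(hit)
    return hits
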