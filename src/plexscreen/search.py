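"""k-mismatch oligo search on reference contigs.

The native backend is an Aho-Corasick automaton (goto/failure/output
links) over the Hamming ball of every expanded oligo variant: for up to k
allowed mismatches, every string within Hamming distance k of the pattern
(and of its reverse complement, for minus-strand placements) is inserted,
so one linear scan of each contig finds every placement exactly — no
heuristic seeding.  Above a configurable total-pattern cap the engine
falls back to a vectorized sliding-window Hamming scan with the identical
hit contract; the pure scanner is also exposed directly as the testing
oracle (:func:`brute_force_scan`).

Coordinates are 1-based, inclusive, always on the plus strand.  Mismatch
offsets count from the oligo's 5' end regardless of strand, and the
reference base in a mismatch entry is read on the oligo's binding strand.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .errors import SearchError
from .oligos import (
    ROLE_PROBE,
    ExpandedOligo,
    Oligo,
    ReferenceSeq,
    expand_degenerate,
    reverse_complement,
)

logger = logging.getLogger(__name__)

METHOD_AHO_CORASICK = "aho_corasick"
METHOD_BLAST = "blast"
METHOD_BOWTIE = "bowtie"

_COMPL = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class Hit:
    """One ungapped placement of an oligo on a reference contig."""

    oligo_name: str
    set_id: str
    role: str
    variant_index: int
    contig_id: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive, plus strand
    end: int  # 1-based inclusive, plus strand
    mismatches: int
    mismatch_repr: str  # "offset:refBase>oligoBase;..." from the oligo 5' end
    matched_ref_seq: str  # plus-strand reference substring [start, end]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (
            self.contig_id,
            self.start,
            self.oligo_name,
            self.strand,
            self.mismatches,
            self.variant_index,
        )


@dataclass(frozen=True)
class SearchConfig:
    """Search method and mismatch limits (0-3 per role)."""

    method: str = METHOD_AHO_CORASICK
    max_mm_primer: int = 0
    max_mm_probe: int = 0
    pattern_cap: int = 5_000_000
    # external adapter knobs (pass-through; see adapters module)
    blast_word_size: int = 7
    blast_qcov_hsp_perc: float = 100.0
    bowtie_seedlen: int = 20
    bowtie_maqerr: int = 70

    def __post_init__(self) -> None:
        if self.method not in (METHOD_AHO_CORASICK, METHOD_BLAST, METHOD_BOWTIE):
            raise SearchError(f"unknown search method {self.method!r}")
        for name in ("max_mm_primer", "max_mm_probe"):
            k = getattr(self, name)
            if not (0 <= k <= 3):
                raise SearchError(f"{name} must be within 0-3, got {k}")

    def max_mismatches(self, role: str) -> int:
        return self.max_mm_probe if role == ROLE_PROBE else self.max_mm_primer


class AhoCorasick:
    """Multi-pattern exact matcher with goto/failure/output links.

    Reports every occurrence of every pattern in one pass over the text;
    identical pattern strings registered under different ids are all
    reported.
    """

    def __init__(self, patterns: list[tuple[object, str]]) -> None:
        if not patterns:
            raise SearchError("cannot build an automaton from an empty pattern list")
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[object]] = [[]]
        for pid, pattern in patterns:
            if not pattern:
                raise SearchError("empty pattern not allowed")
            self.add(pid, pattern)
        self._built = False

    def add(self, pid: object, pattern: str) -> None:
        goto = self._goto
        out = self._out
        state = 0
        for ch in pattern:
            nxt = goto[state].get(ch)
            if nxt is None:
                nxt = len(goto)
                goto.append({})
                out.append([])
                goto[state][ch] = nxt
            state = nxt
        out[state].append(pid)
        self._built = False

    def _build(self) -> None:
        goto = self._goto
        out = self._out
        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for state in goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in goto[state].items():
                queue.append(nxt)
                f = fail[state]
                while f and ch not in goto[f]:
                    f = fail[f]
                fail[nxt] = goto[f].get(ch, 0)
                if fail[nxt] == nxt:
                    fail[nxt] = 0
                if out[fail[nxt]]:
                    out[nxt] = out[nxt] + out[fail[nxt]]
        self._fail = fail
        self._built = True

    def iter_matches(self, text: str):
        """Yield ``(pattern_id, end_position)`` (0-based inclusive end)."""
        if not self._built:
            self._build()
        goto = self._goto
        out = self._out
        fail = self._fail
        state = 0
        for pos, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            if out[state]:
                for pid in out[state]:
                    yield pid, pos


def build_automaton(patterns: list[tuple[object, str]]) -> AhoCorasick:
    """Build an Aho-Corasick matcher over ``(pattern_id, ACGT string)``."""
    return AhoCorasick(patterns)


def hamming_ball_size(length: int, k: int, alphabet_size: int = 4) -> int:
    """Number of strings within Hamming distance k: sum C(L,i)*(a-1)^i."""
    m = alphabet_size - 1
    return sum(math.comb(length, i) * m**i for i in range(k + 1))


def enumerate_mismatch_variants(
    pattern: str, k: int, *, cap: int = 5_000_000, alphabet: str = "ACGT"
) -> dict[str, int]:
    """All strings within Hamming distance k of ``pattern``, with distances.

    Exact enumeration over substitutions from ``alphabet``; the count is
    sum_{i=0..k} C(L, i) * (|alphabet| - 1)^i.  Exceeding ``cap`` is fatal
    (use a lower k or the brute-force scanner).
    """
    if k < 0:
        raise SearchError("k must be >= 0")
    size = hamming_ball_size(len(pattern), k, len(alphabet))
    if size > cap:
        raise SearchError(
            f"Hamming ball of {pattern!r} at k={k} has {size} members "
            f"(cap {cap}); lower k or use the brute-force scanner"
        )
    result: dict[str, int] = {pattern: 0}
    chars = list(pattern)
    positions = range(len(pattern))
    for d in range(1, k + 1):
        for pos_combo in combinations(positions, d):
            subs = [[c for c in alphabet if c != chars[p]] for p in pos_combo]
            for repl in product(*subs):
                variant = chars.copy()
                for p, c in zip(pos_combo, repl):
                    variant[p] = c
                result["".join(variant)] = d
    return result


def _mismatch_repr(window: str, oriented_pattern: str, strand: str) -> str:
    """Encode mismatches as "offset:refBase>oligoBase" from the oligo 5' end.

    ``oriented_pattern`` is the oligo variant as scanned on the plus
    strand (the reverse complement of the variant for minus-strand hits);
    the reference base is reported on the oligo's binding strand.
    """
    length = len(window)
    entries = []
    for j in range(length):
        if window[j] != oriented_pattern[j]:
            if strand == "+":
                offset = j + 1
                ref_base = window[j]
                oligo_base = oriented_pattern[j]
            else:
                offset = length - j
                ref_base = _COMPL[window[j]]
                oligo_base = _COMPL[oriented_pattern[j]]
            entries.append((offset, ref_base, oligo_base))
    entries.sort()
    return ";".join(f"{o}:{r}>{q}" for o, r, q in entries)


def brute_force_scan(
    pattern: str,
    reference: ReferenceSeq,
    k: int,
    *,
    oligo_name: str | None = None,
    set_id: str = "",
    role: str = "forward_primer",
    variant_index: int = 0,
) -> list[Hit]:
    """Sliding-window Hamming scan of one concrete pattern, both strands.

    Intentionally simple (vectorized window comparison at every position);
    serves as the ground-truth oracle for the automaton backend.  Returns
    the same Hit records as :func:`search_references`, unsorted.
    """
    name = oligo_name if oligo_name is not None else pattern
    length = len(pattern)
    text = reference.sequence
    if len(text) < length:
        return []
    text_arr = np.frombuffer(text.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(text_arr, length)
    hits: list[Hit] = []
    rc = reverse_complement(pattern)
    for strand, oriented in (("+", pattern), ("-", rc)):
        pat_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
        mm_counts = (windows != pat_arr).sum(axis=1)
        for pos in np.nonzero(mm_counts <= k)[0]:
            start = int(pos) + 1
            window = text[pos : pos + length]
            hits.append(
                Hit(
                    oligo_name=name,
                    set_id=set_id,
                    role=role,
                    variant_index=variant_index,
                    contig_id=reference.contig_id,
                    strand=strand,
                    start=start,
                    end=start + length - 1,
                    mismatches=int(mm_counts[pos]),
                    mismatch_repr=_mismatch_repr(window, oriented, strand),
                    matched_ref_seq=window,
                )
            )
    return hits


def _search_brute(
    variants: list[tuple[Oligo, ExpandedOligo, int]],
    references: list[ReferenceSeq],
) -> list[Hit]:
    hits: list[Hit] = []
    for oligo, variant, k in variants:
        for ref in references:
            hits.extend(
                brute_force_scan(
                    variant.sequence,
                    ref,
                    k,
                    oligo_name=oligo.name,
                    set_id=oligo.set_id,
                    role=oligo.role,
                    variant_index=variant.variant_index,
                )
            )
    return hits


def _search_automaton(
    variants: list[tuple[Oligo, ExpandedOligo, int]],
    references: list[ReferenceSeq],
    substitution_alphabet: str,
) -> list[Hit]:
    # payload: (oligo, variant_index, strand, oriented variant sequence)
    by_string: dict[str, list[tuple[Oligo, int, str, str]]] = {}
    for oligo, variant, k in variants:
        for strand, oriented in (
            ("+", variant.sequence),
            ("-", reverse_complement(variant.sequence)),
        ):
            payload = (oligo, variant.variant_index, strand, oriented)
            for string in enumerate_mismatch_variants(
                oriented, k, alphabet=substitution_alphabet
            ):
                by_string.setdefault(string, []).append(payload)
    automaton = AhoCorasick(
        [(payloads, string) for string, payloads in by_string.items()]
    )
    hits: list[Hit] = []
    for ref in references:
        text = ref.sequence
        for payloads, end_pos in automaton.iter_matches(text):
            for oligo, variant_index, strand, oriented in payloads:
                length = len(oriented)
                start = end_pos - length + 2  # 1-based
                window = text[end_pos - length + 1 : end_pos + 1]
                mm_repr = _mismatch_repr(window, oriented, strand)
                hits.append(
                    Hit(
                        oligo_name=oligo.name,
                        set_id=oligo.set_id,
                        role=oligo.role,
                        variant_index=variant_index,
                        contig_id=ref.contig_id,
                        strand=strand,
                        start=start,
                        end=start + length - 1,
                        mismatches=mm_repr.count(":"),
                        mismatch_repr=mm_repr,
                        matched_ref_seq=window,
                    )
                )
    return hits


def search_references(
    oligos: list[Oligo],
    references: list[ReferenceSeq],
    config: SearchConfig,
    *,
    expansion_cap: int = 1024,
) -> list[Hit]:
    """Find all placements of every oligo on every contig, both strands.

    Each oligo is expanded to its concrete IUPAC variants and searched
    with the role-specific mismatch limit.  The result carries every
    placement with <= k mismatches per variant (deduplication across
    variants is a separate, explicit step), deterministically sorted by
    (contig_id, start, oligo_name, strand).

    Reference N bases count as mismatches against every oligo base; when
    any contig contains N the automaton's substitution alphabet includes N
    so N-containing windows remain reachable and the backend stays exactly
    equivalent to the brute-force scanner.
    """
    variants: list[tuple[Oligo, ExpandedOligo, int]] = []
    for oligo in oligos:
        k = config.max_mismatches(oligo.role)
        for variant in expand_degenerate(oligo, cap=expansion_cap):
            variants.append((oligo, variant, k))
    refs_have_n = any("N" in ref.sequence for ref in references)
    alphabet = "ACGTN" if refs_have_n else "ACGT"
    total_patterns = sum(
        2 * hamming_ball_size(len(v.sequence), k, len(alphabet))
        for _, v, k in variants
    )
    if total_patterns > config.pattern_cap:
        logger.info(
            "pattern count %d exceeds cap %d; using brute-force scanner",
            total_patterns,
            config.pattern_cap,
        )
        hits = _search_brute(variants, references)
    elif variants:
        hits = _search_automaton(variants, references, alphabet)
    else:
        hits = []
    hits.sort(key=Hit.sort_key)
    return hits


def deduplicate_hits(hits: list[Hit]) -> list[Hit]:
    """Collapse variant hits: one Hit per (oligo, contig, start, strand).

    The retained hit has the minimal mismatch count among collapsing
    variants; ties break to the lowest variant index.  Idempotent.
    """
    best: dict[tuple[str, str, int, str], Hit] = {}
    for hit in hits:
        key = (hit.oligo_name, hit.contig_id, hit.start, hit.strand)
        current = best.get(key)
        if current is None or (hit.mismatches, hit.variant_index) < (
            current.mismatches,
            current.variant_index,
        ):
            best[key] = hit
    out = list(best.values())
    out.sort(key=Hit.sort_key)
    return out
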