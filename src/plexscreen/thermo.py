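"""Nearest-neighbor duplex thermodynamics and secondary-structure screening.

The model is the SantaLucia unified nearest-neighbor scheme: duplex
enthalpy and entropy are sums of dinucleotide stack terms plus terminal
initiation terms (and a symmetry term for self-complementary duplexes).
Single internal mismatches are scored with the published mismatch stacks;
tandem and terminal mismatches are outside the model.  Ionic strength
enters as an entropy correction

    dS_corr = dS + 0.368 * (N - 1) * ln([Na+]_eq)

with the divalent/dNTP pool converted to a monovalent equivalent by
``[Na+]_eq = [mono] + 120 * sqrt([divalent] - [dNTP])`` (all mM).

Melting temperatures use

    Tm = 1000 * dH / (dS_corr + R * ln(CT / x)) - 273.15

with x = 4 for non-self-complementary duplexes, x = 1 for
self-complementary ones, and no concentration term for (unimolecular)
hairpins.

Dimer screening is exhaustive over all antiparallel ungapped offsets of
the two sequences; within each offset every window that starts and ends
on a Watson-Crick pair and contains no adjacent mismatches is scored, and
the window minimizing dG at the step's annealing temperature is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ThermoError
from .oligos import Oligo, expand_degenerate
from .params import (
    R_GAS,
    NNParameterTable,
    complement_acgt,
    default_loop_table,
    default_nn_table,
    is_wc,
)

STEP_AMPLIFICATION = "amplification"
STEP_HYBRIDIZATION = "hybridization"


@dataclass(frozen=True)
class Conditions:
    """Temperature and concentration context of one assay step.

    annealing_temp in degrees C; monovalent/divalent/dntp in mM;
    oligo_conc (total single-strand concentration CT) in nM.
    """

    step: str = STEP_AMPLIFICATION
    annealing_temp: float = 55.0
    monovalent: float = 50.0
    divalent: float = 1.5
    dntp: float = 0.8
    oligo_conc: float = 250.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.annealing_temp <= 100.0):
            raise ThermoError("annealing temperature must be within 0-100 C")
        for name in ("monovalent", "divalent", "dntp", "oligo_conc"):
            if getattr(self, name) < 0:
                raise ThermoError(f"{name} concentration must be >= 0")


@dataclass(frozen=True)
class ThermoResult:
    """dH/dS/dG/Tm of one duplex, dimer, or hairpin structure.

    dS is the salt-corrected entropy; dG_at_temp is evaluated at the
    step's annealing temperature, dG37 at 37 C.  ``tm`` is None when the
    melting temperature is undefined (e.g. no stable structure).
    ``structure`` renders the scored alignment with mismatched columns in
    lowercase (``TOP/BOTTOM``, bottom written 3'->5'); hairpins use
    ``dangling5 STEM ( loop ) STEM dangling3`` with dangling bases in
    lowercase.
    """

    dH: float
    dS: float
    dG_at_temp: float
    dG37: float
    tm: float | None
    structure: str
    variant_indices: tuple[int, ...] = ()

    @property
    def is_empty(self) -> bool:
        return self.structure == ""


EMPTY_RESULT = ThermoResult(0.0, 0.0, 0.0, 0.0, None, "")


def salt_correction(monovalent: float, divalent: float, dntp: float) -> float:
    """Monovalent-equivalent cation concentration (mM).

    Free divalent ions (above the dNTP chelation pool) count with weight
    120 * sqrt(.): Na_eq = mono + 120 * sqrt(max(0, divalent - dntp)).
    """
    if min(monovalent, divalent, dntp) < 0:
        raise ThermoError("ion concentrations must be >= 0")
    na_eq = monovalent + 120.0 * math.sqrt(max(0.0, divalent - dntp))
    if na_eq <= 0:
        raise ThermoError(
            "effective monovalent cation concentration is zero; "
            "supply monovalent or free divalent ions"
        )
    return na_eq


def _entropy_salt_term(n_paired: int, na_eq_mm: float) -> float:
    return 0.368 * (n_paired - 1) * math.log(na_eq_mm / 1000.0)


def _finish(
    dh: float,
    ds: float,
    n_paired: int,
    conditions: Conditions,
    *,
    self_complementary: bool,
    unimolecular: bool,
    structure: str,
) -> ThermoResult:
    na_eq = salt_correction(conditions.monovalent, conditions.divalent, conditions.dntp)
    ds_corr = ds + _entropy_salt_term(n_paired, na_eq)
    t_anneal = conditions.annealing_temp + 273.15
    dg_at = dh - t_anneal * ds_corr / 1000.0
    dg37 = dh - 310.15 * ds_corr / 1000.0
    if unimolecular:
        denom = ds_corr
    else:
        ct = conditions.oligo_conc * 1e-9
        x = 1.0 if self_complementary else 4.0
        denom = ds_corr + R_GAS * math.log(ct / x)
    tm = 1000.0 * dh / denom - 273.15 if denom != 0 else None
    return ThermoResult(dh, ds_corr, dg_at, dg37, tm, structure)


def _column_states(top: str, bottom: str) -> list[bool]:
    return [is_wc(t, b) for t, b in zip(top, bottom)]


def _mark_mismatch_lower(seq: str, wc: list[bool]) -> str:
    return "".join(c if ok else c.lower() for c, ok in zip(seq, wc))


def duplex_thermo(
    top: str,
    bottom: str,
    conditions: Conditions,
    table: NNParameterTable | None = None,
) -> ThermoResult:
    """Score a base-by-base aligned duplex.

    ``top`` is 5'->3', ``bottom`` is the aligned complementary strand
    written 3'->5'.  Terminal columns must be Watson-Crick; internal
    mismatches must be isolated (no tandem mismatches).
    """
    table = table or default_nn_table()
    if len(top) != len(bottom):
        raise ThermoError("duplex strands must have equal lengths")
    if len(top) < 2:
        raise ThermoError("duplex must have at least two base pairs")
    wc = _column_states(top, bottom)
    if not wc[0] or not wc[-1]:
        raise ThermoError("terminal mismatch: callers must trim to a WC-anchored core")
    for i in range(len(wc) - 1):
        if not wc[i] and not wc[i + 1]:
            raise ThermoError("tandem mismatch unsupported")
    dh, ds = 0.0, 0.0
    for i in range(len(top) - 1):
        h, s = table.stack(top[i : i + 2], bottom[i : i + 2])
        dh += h
        ds += s
    for end in (0, len(top) - 1):
        h, s = table.initiation(top[end], bottom[end])
        dh += h
        ds += s
    self_comp = top == bottom[::-1]
    if self_comp:
        dh += table.sym[0]
        ds += table.sym[1]
    structure = (
        _mark_mismatch_lower(top, wc) + "/" + _mark_mismatch_lower(bottom, wc)
    )
    return _finish(
        dh,
        ds,
        len(top),
        conditions,
        self_complementary=self_comp,
        unimolecular=False,
        structure=structure,
    )


# ---------------------------------------------------------------------------
# dimer screening


def _best_window_for_offset(
    seq1: str,
    b: str,
    offset: int,
    conditions: Conditions,
    table: NNParameterTable,
    na_eq: float,
) -> tuple[float, int, int] | None:
    """Best (dG_at_temp, window start, window end) at one antiparallel offset.

    ``b`` is seq2 reversed, so column i of the overlap pairs seq1[i] with
    b[i - offset].  Returns None when no legal window exists.
    """
    lo = max(0, offset)
    hi = min(len(seq1), offset + len(b))
    if hi - lo < 2:
        return None
    top = seq1[lo:hi]
    bot = b[lo - offset : hi - offset]
    wc = _column_states(top, bot)
    n = len(top)
    # stack sums between adjacent columns; None marks a tandem-mismatch gap
    cum_h = [0.0] * n
    cum_s = [0.0] * n
    breaks = [False] * (n - 1)
    for i in range(n - 1):
        if not wc[i] and not wc[i + 1]:
            breaks[i] = True
            cum_h[i + 1] = cum_h[i]
            cum_s[i + 1] = cum_s[i]
        else:
            h, s = table.stack(top[i : i + 2], bot[i : i + 2])
            cum_h[i + 1] = cum_h[i] + h
            cum_s[i + 1] = cum_s[i] + s
    t_anneal = conditions.annealing_temp + 273.15
    best: tuple[float, int, int] | None = None
    seg_start = 0
    segments = []
    for i in range(n - 1):
        if breaks[i]:
            segments.append((seg_start, i))
            seg_start = i + 1
    segments.append((seg_start, n - 1))
    for s0, s1 in segments:
        wc_idx = [i for i in range(s0, s1 + 1) if wc[i]]
        for ai in range(len(wc_idx) - 1):
            a = wc_idx[ai]
            h_init_a, s_init_a = table.initiation(top[a], bot[a])
            for ci in range(ai + 1, len(wc_idx)):
                c = wc_idx[ci]
                dh = cum_h[c] - cum_h[a] + h_init_a
                ds = cum_s[c] - cum_s[a] + s_init_a
                h2, s2 = table.initiation(top[c], bot[c])
                dh += h2
                ds += s2
                if top[a : c + 1] == bot[a : c + 1][::-1]:
                    dh += table.sym[0]
                    ds += table.sym[1]
                ds_corr = ds + _entropy_salt_term(c - a + 1, na_eq)
                dg = dh - t_anneal * ds_corr / 1000.0
                if best is None or dg < best[0]:
                    best = (dg, lo + a, lo + c)
    return best


def _best_dimer(seq1: str, seq2: str, conditions: Conditions,
                table: NNParameterTable) -> ThermoResult:
    b = seq2[::-1]
    na_eq = salt_correction(conditions.monovalent, conditions.divalent, conditions.dntp)
    best: tuple[float, int, int, int] | None = None
    for offset in range(-(len(seq2) - 1), len(seq1)):
        cand = _best_window_for_offset(seq1, b, offset, conditions, table, na_eq)
        if cand is not None and (best is None or cand[0] < best[0]):
            best = (cand[0], offset, cand[1], cand[2])
    if best is None or best[0] >= 0:
        return EMPTY_RESULT
    _, offset, a, c = best
    top = seq1[a : c + 1]
    bot = b[a - offset : c - offset + 1]
    return duplex_thermo(top, bot, conditions, table)


def self_dimer(
    oligo: Oligo | str,
    conditions: Conditions,
    table: NNParameterTable | None = None,
) -> ThermoResult:
    """Most stable antiparallel self-duplex of an oligo (or dG=0 result)."""
    return cross_dimer(oligo, oligo, conditions, table)


def cross_dimer(
    oligo1: Oligo | str,
    oligo2: Oligo | str,
    conditions: Conditions,
    table: NNParameterTable | None = None,
) -> ThermoResult:
    """Most stable antiparallel duplex between two oligos (or dG=0 result).

    Degenerate oligos are screened through their most stable expanded
    variant (see :func:`screening_variant`); the chosen variant indices
    are reported on the result.
    """
    table = table or default_nn_table()
    s1, v1 = _screening_sequence(oligo1)
    s2, v2 = _screening_sequence(oligo2)
    result = _best_dimer(s1, s2, conditions, table)
    return replace(result, variant_indices=(v1, v2))


def hairpin(
    oligo: Oligo | str,
    conditions: Conditions,
    table: NNParameterTable | None = None,
    *,
    min_stem: int = 3,
    min_loop: int = 3,
) -> ThermoResult:
    """Most stable stem-loop of a single oligo.

    Enumerates every decomposition with a Watson-Crick stem of >=
    ``min_stem`` bp and a loop of >= ``min_loop`` bases (dangling ends
    allowed); stems are scored with NN stacks, loops with the tabulated
    entropic initiation penalty.  Unimolecular: Tm has no concentration
    term.  The minimum-dG structure is reported even when dG > 0 so the
    Tm-proximity flagging rule can apply; with no legal structure a dG=0
    empty result is returned.
    """
    table = table or default_nn_table()
    loops = default_loop_table()
    seq, variant = _screening_sequence(oligo)
    length = len(seq)
    na_eq = salt_correction(conditions.monovalent, conditions.divalent, conditions.dntp)
    t_anneal = conditions.annealing_temp + 273.15
    best: tuple[float, int, int, int] | None = None  # dG, arm1 start, stem, arm2 start
    for i in range(length):
        max_stem = (length - i - min_loop) // 2
        for s in range(min_stem, max_stem + 1):
            arm1 = seq[i : i + s]
            comp = complement_acgt(arm1)
            target = comp[::-1]  # required 3' arm read 5'->3'
            for j in range(i + s + min_loop, length - s + 1):
                if seq[j : j + s] != target:
                    continue
                dh, ds = 0.0, 0.0
                bottom = comp  # 3'->5' alignment of the stem duplex
                for p in range(s - 1):
                    h, st = table.stack(arm1[p : p + 2], bottom[p : p + 2])
                    dh += h
                    ds += st
                loop_len = j - (i + s)
                ds += -1000.0 * loops.loop_dg37(loop_len) / 310.15
                ds_corr = ds + _entropy_salt_term(s, na_eq)
                dg = dh - t_anneal * ds_corr / 1000.0
                if best is None or dg < best[0]:
                    best = (dg, i, s, j)
    if best is None:
        return EMPTY_RESULT
    _, i, s, j = best
    arm1 = seq[i : i + s]
    bottom = complement_acgt(arm1)
    dh, ds = 0.0, 0.0
    for p in range(s - 1):
        h, st = table.stack(arm1[p : p + 2], bottom[p : p + 2])
        dh += h
        ds += st
    ds += -1000.0 * loops.loop_dg37(j - (i + s)) / 310.15
    structure = (
        seq[:i].lower()
        + arm1
        + "("
        + seq[i + s : j]
        + ")"
        + seq[j : j + s]
        + seq[j + s :].lower()
    )
    result = _finish(
        dh,
        ds,
        s,
        conditions,
        self_complementary=False,
        unimolecular=True,
        structure=structure,
    )
    return replace(result, variant_indices=(variant,))


# ---------------------------------------------------------------------------
# degenerate screening variant and panel-wide screening


def screening_variant(oligo: Oligo) -> tuple[str, int]:
    """Concrete sequence used to screen a (possibly degenerate) oligo.

    The most stable expanded variant: the one whose perfect-match duplex
    has the lowest (uncorrected) dG37.  Ties break to the lowest variant
    index; a non-degenerate oligo is its own variant 0.
    """
    if not oligo.is_degenerate:
        return oligo.sequence, 0
    table = default_nn_table()
    best: tuple[float, int, str] | None = None
    for var in expand_degenerate(oligo):
        seq = var.sequence
        bottom = complement_acgt(seq)
        dh, ds = 0.0, 0.0
        for i in range(len(seq) - 1):
            h, s = table.stack(seq[i : i + 2], bottom[i : i + 2])
            dh += h
            ds += s
        for end in (0, len(seq) - 1):
            h, s = table.initiation(seq[end], bottom[end])
            dh += h
            ds += s
        dg37 = dh - 310.15 * ds / 1000.0
        if best is None or dg37 < best[0]:
            best = (dg37, var.variant_index, seq)
    assert best is not None
    return best[2], best[1]


def _screening_sequence(oligo: Oligo | str) -> tuple[str, int]:
    if isinstance(oligo, str):
        return oligo, 0
    return screening_variant(oligo)


@dataclass(frozen=True)
class ScreenThresholds:
    """Reporting thresholds for flagged secondary structures (kcal/mol, C)."""

    cross_dg: float = -9.0
    self_dg: float = -5.0
    hairpin_dg: float = -5.0
    hairpin_tm_margin: float = 3.0


@dataclass(frozen=True)
class FlaggedStructure:
    step: str
    kind: str  # self_dimer | cross_dimer | hairpin
    oligo1: str
    oligo2: str | None
    result: ThermoResult
    reason: str


def flag_reasons(
    kind: str,
    result: ThermoResult,
    conditions: Conditions,
    thresholds: ScreenThresholds | None = None,
) -> list[str]:
    """Reporting rules for one predicted structure; empty list = not flagged.

    Cross-dimers are flagged at dG <= -9 kcal/mol, self-dimers and
    hairpins at dG <= -5 kcal/mol, and hairpins additionally whenever
    Tm + margin reaches the step's annealing temperature.  Structures
    with no stable window are never flagged.
    """
    thresholds = thresholds or ScreenThresholds()
    if result.is_empty:
        return []
    reasons: list[str] = []
    if kind == "cross_dimer":
        if result.dG_at_temp <= thresholds.cross_dg:
            reasons.append(f"dG <= {thresholds.cross_dg:g} kcal/mol")
    elif kind == "self_dimer":
        if result.dG_at_temp <= thresholds.self_dg:
            reasons.append(f"dG <= {thresholds.self_dg:g} kcal/mol")
    elif kind == "hairpin":
        if result.dG_at_temp <= thresholds.hairpin_dg:
            reasons.append(f"dG <= {thresholds.hairpin_dg:g} kcal/mol")
        if (
            result.tm is not None
            and result.tm + thresholds.hairpin_tm_margin >= conditions.annealing_temp
        ):
            reasons.append(
                f"Tm + {thresholds.hairpin_tm_margin:g} >= annealing temperature"
            )
    else:
        raise ThermoError(f"unknown structure kind {kind!r}")
    return reasons


@dataclass
class StepScreen:
    """All secondary-structure predictions for one assay step."""

    conditions: Conditions
    self_dimers: dict[str, ThermoResult] = field(default_factory=dict)
    cross_dimers: dict[tuple[str, str], ThermoResult] = field(default_factory=dict)
    hairpins: dict[str, ThermoResult] = field(default_factory=dict)
    flagged: list[FlaggedStructure] = field(default_factory=list)


def screen_panel(
    oligos: list[Oligo],
    conditions_list: list[Conditions],
    thresholds: ScreenThresholds | None = None,
    table: NNParameterTable | None = None,
) -> list[StepScreen]:
    """Self-dimer, cross-dimer, and hairpin screen of a whole oligo panel.

    Every oligo and every unordered pair is screened at each step's
    conditions.  Flagging defaults: cross-dimer dG <= -9 kcal/mol,
    self-dimer dG <= -5, hairpin dG <= -5 or Tm + 3 >= step annealing
    temperature.
    """
    thresholds = thresholds or ScreenThresholds()
    table = table or default_nn_table()
    screens: list[StepScreen] = []
    for conditions in conditions_list:
        screen = StepScreen(conditions=conditions)
        for oligo in oligos:
            res = self_dimer(oligo, conditions, table)
            screen.self_dimers[oligo.name] = res
            reasons = flag_reasons("self_dimer", res, conditions, thresholds)
            if reasons:
                screen.flagged.append(
                    FlaggedStructure(
                        conditions.step, "self_dimer", oligo.name, None, res,
                        "; ".join(reasons),
                    )
                )
        for i, o1 in enumerate(oligos):
            for o2 in oligos[i + 1 :]:
                res = cross_dimer(o1, o2, conditions, table)
                screen.cross_dimers[(o1.name, o2.name)] = res
                reasons = flag_reasons("cross_dimer", res, conditions, thresholds)
                if reasons:
                    screen.flagged.append(
                        FlaggedStructure(
                            conditions.step, "cross_dimer", o1.name, o2.name, res,
                            "; ".join(reasons),
                        )
                    )
        for oligo in oligos:
            res = hairpin(oligo, conditions, table)
            screen.hairpins[oligo.name] = res
            reasons = flag_reasons("hairpin", res, conditions, thresholds)
            if reasons:
                screen.flagged.append(
                    FlaggedStructure(
                        conditions.step, "hairpin", oligo.name, None, res,
                        "; ".join(reasons),
                    )
                )
        screens.append(screen)
    return screens


def hit_duplex_thermo(
    oligo_seq: str,
    matched_ref_seq: str,
    strand: str,
    conditions: Conditions,
    table: NNParameterTable | None = None,
) -> ThermoResult | None:
    """Thermodynamics of an oligo bound at one search hit.

    Builds the oligo/template duplex from the plus-strand reference
    substring, trims terminal mismatches to the Watson-Crick-anchored
    core, and scores it.  Returns None when the model cannot score the
    alignment (N bases, tandem mismatches, or no WC core of >= 2 bp).
    """
    if any(c not in "ACGT" for c in matched_ref_seq):
        return None
    if strand == "-":
        ref_on_strand = complement_acgt(matched_ref_seq)[::-1]
    else:
        ref_on_strand = matched_ref_seq
    bottom = complement_acgt(ref_on_strand)
    top = oligo_seq
    lo, hi = 0, len(top)
    while lo < hi and not is_wc(top[lo], bottom[lo]):
        lo += 1
    while hi > lo and not is_wc(top[hi - 1], bottom[hi - 1]):
        hi -= 1
    if hi - lo < 2:
        return None
    try:
        return duplex_thermo(top[lo:hi], bottom[lo:hi], conditions, table)
    except ThermoError:
        return None
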