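"""Nearest-neighbor thermodynamics: parameter-table integrity (checked
exhaustively against an independent published copy), duplex scoring,
salt correction, dimer/hairpin screening, and flagging thresholds."""

import itertools
import math
import random

import pytest
from Bio.SeqUtils import MeltingTemp as mt

from plexscreen.errors import ThermoError
from plexscreen.oligos import Oligo, reverse_complement
from plexscreen.params import (
    R_GAS,
    complement_acgt,
    default_loop_table,
    default_nn_table,
    rotate_stack,
)
from plexscreen.thermo import (
    Conditions,
    ScreenThresholds,
    ThermoResult,
    cross_dimer,
    duplex_thermo,
    flag_reasons,
    hairpin,
    hit_duplex_thermo,
    salt_correction,
    screen_panel,
    self_dimer,
)

STD = Conditions(annealing_temp=37.0, monovalent=1000.0, divalent=0.0,
                 dntp=0.0, oligo_conc=250.0)


def random_acgt(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))


class TestParameterTable:
    def test_watson_crick_matches_independent_copy(self):
        """All 16 WC stacks equal the published values Biopython ships."""
        table = default_nn_table()
        assert len(table.wc) == 16
        for key, value in table.wc.items():
            ref = mt.DNA_NN3.get(key) or mt.DNA_NN3.get(rotate_stack(key))
            assert ref is not None, key
            assert value == tuple(ref)

    def test_mismatch_stacks_match_independent_copy(self):
        table = default_nn_table()
        for key, value in table.mismatch.items():
            ref = mt.DNA_IMM1.get(key) or mt.DNA_IMM1.get(rotate_stack(key))
            assert ref is not None, key
            assert value == tuple(ref)

    def test_initiation_and_symmetry_terms(self):
        table = default_nn_table()
        assert table.init_at == tuple(mt.DNA_NN3["init_A/T"])
        assert table.init_gc == tuple(mt.DNA_NN3["init_G/C"])
        assert table.sym == tuple(mt.DNA_NN3["sym"])

    def test_strand_symmetry_identity_exhaustive(self):
        """Every WC stack equals its 180-degree rotation."""
        table = default_nn_table()
        for key, value in table.wc.items():
            assert table.wc[rotate_stack(key)] == value

    def test_every_single_mismatch_context_is_scorable(self):
        """Each WC flank x mismatch combination resolves, both sides."""
        table = default_nn_table()
        wc_pairs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
        mismatch_pairs = [
            (t, b)
            for t, b in itertools.product("ACGT", repeat=2)
            if (t, b) not in wc_pairs
        ]
        for (lt, lb), (mt_, mb) in itertools.product(wc_pairs, mismatch_pairs):
            table.stack(lt + mt_, lb + mb)  # WC then mismatch
            table.stack(mt_ + lt, mb + lb)  # mismatch then WC


class TestSaltCorrection:
    def test_divalent_conversion(self):
        assert salt_correction(50, 1.5, 0.8) == pytest.approx(
            50 + 120 * math.sqrt(0.7), abs=1e-9
        )

    def test_no_divalent(self):
        assert salt_correction(50, 0, 0) == 50.0

    def test_dntp_chelation_floor(self):
        assert salt_correction(50, 0.5, 0.8) == 50.0

    def test_zero_ionic_strength_fatal(self):
        with pytest.raises(ThermoError, match="zero"):
            salt_correction(0, 0, 0)


class TestDuplexThermo:
    def test_perfect_gcgc_hand_sum(self):
        """GC+CG+GC stacks + two G/C initiations + symmetry term."""
        result = duplex_thermo("GCGC", complement_acgt("GCGC"), STD)
        assert result.dH == pytest.approx(-9.8 - 10.6 - 9.8 + 0.1 + 0.1, abs=1e-12)
        ds = -24.4 - 27.2 - 24.4 - 2.8 - 2.8 - 1.4  # includes sym (self-comp.)
        assert result.dS == pytest.approx(ds, abs=1e-9)  # 1 M Na+: no salt shift
        assert result.dG37 == pytest.approx(result.dH - 310.15 * ds / 1000, abs=1e-9)

    def test_strand_symmetry_of_duplexes(self):
        rng = random.Random(5)
        for _ in range(20):
            top = random_acgt(rng, rng.randint(8, 20))
            bottom = complement_acgt(top)
            a = duplex_thermo(top, bottom, STD)
            # the same physical duplex entered with strands swapped
            b = duplex_thermo(bottom[::-1], top[::-1], STD)
            assert a.dH == pytest.approx(b.dH, abs=1e-9)
            assert a.dS == pytest.approx(b.dS, abs=1e-9)

    def test_tandem_mismatch_rejected(self):
        # columns 2 and 3 (C.C, C.C) are adjacent mismatches
        with pytest.raises(ThermoError, match="tandem"):
            duplex_thermo("ACCGA", "TCCCT", STD)

    def test_terminal_mismatch_rejected(self):
        with pytest.raises(ThermoError, match="terminal"):
            duplex_thermo("ACGT", "AGCA", STD)

    def test_tm_agrees_with_independent_calculator(self):
        """Perfect-duplex Tm within 0.05 C of Biopython's NN calculator
        (same published table, same entropy salt correction)."""
        rng = random.Random(17)
        for _ in range(50):
            seq = random_acgt(rng, rng.randint(15, 30))
            if seq == reverse_complement(seq):
                continue
            for na in (1000.0, 150.0, 50.0):
                conditions = Conditions(
                    annealing_temp=37, monovalent=na, divalent=0, dntp=0,
                    oligo_conc=250,
                )
                mine = duplex_thermo(seq, complement_acgt(seq), conditions).tm
                ref = mt.Tm_NN(
                    seq, nn_table=mt.DNA_NN3, dnac1=125, dnac2=125,
                    Na=na, Mg=0, dNTPs=0, saltcorr=5,
                )
                assert mine == pytest.approx(ref, abs=0.05)

    def test_tm_monotone_in_salt_and_concentration(self):
        seq = "ACGTGCTAGCTAAGGCTT"
        tms_na = [
            duplex_thermo(
                seq, complement_acgt(seq),
                Conditions(annealing_temp=37, monovalent=na, divalent=0,
                           dntp=0, oligo_conc=250),
            ).tm
            for na in (10, 50, 150, 500, 1000)
        ]
        assert tms_na == sorted(tms_na)
        tms_ct = [
            duplex_thermo(
                seq, complement_acgt(seq),
                Conditions(annealing_temp=37, monovalent=50, divalent=0,
                           dntp=0, oligo_conc=ct),
            ).tm
            for ct in (10, 100, 1000, 10000)
        ]
        assert tms_ct == sorted(tms_ct)

    def test_dg37_identity(self):
        rng = random.Random(23)
        for _ in range(30):
            seq = random_acgt(rng, rng.randint(6, 25))
            res = duplex_thermo(seq, complement_acgt(seq), STD)
            assert res.dG37 == pytest.approx(
                res.dH - 310.15 * res.dS / 1000.0, abs=1e-9
            )


def gg_mismatch_minimum_dg37() -> float:
    """Most stabilizing single internal G.G mismatch over all WC flanks.

    The mismatch contributes through its two flanking stacks; the minimum
    of the two-stack dG37 sum over all 4 x 4 flank contexts.
    """
    table = default_nn_table()
    best = math.inf
    for left, right in itertools.product("ACGT", repeat=2):
        lh, ls = table.stack(left + "G", complement_acgt(left) + "G")
        rh, rs = table.stack("G" + right, "G" + complement_acgt(right))
        dg = (lh - 310.15 * ls / 1000.0) + (rh - 310.15 * rs / 1000.0)
        best = min(best, dg)
    return best


class TestMismatchStabilization:
    def test_gg_minimum_is_minus_2_2(self):
        assert round(gg_mismatch_minimum_dg37(), 1) == -2.2

    def test_single_gg_duplex_scores(self):
        # G.G mismatch in its most stabilizing context, flanked by WC pairs
        result = duplex_thermo("AGGCA", "TCGGT", STD)
        assert result.dH < 0


def brute_force_best_dimer(seq1, seq2, conditions):
    """Independent exhaustive dimer enumeration: all offsets, all windows,
    each window scored through duplex_thermo directly."""
    b = seq2[::-1]
    best = None
    for offset in range(-(len(seq2) - 1), len(seq1)):
        lo, hi = max(0, offset), min(len(seq1), offset + len(seq2))
        for a in range(lo, hi):
            for c in range(a + 1, hi):
                top = seq1[a : c + 1]
                bot = b[a - offset : c - offset + 1]
                try:
                    res = duplex_thermo(top, bot, conditions)
                except ThermoError:
                    continue
                if best is None or res.dG_at_temp < best.dG_at_temp:
                    best = res
    if best is None or best.dG_at_temp >= 0:
        return 0.0
    return best.dG_at_temp


class TestDimers:
    def test_no_complementarity_gives_zero(self):
        assert self_dimer("AAAAAA", STD).dG_at_temp == 0.0
        assert cross_dimer("AAAAAA", "CCCCCC", STD).dG_at_temp == 0.0

    def test_self_complementary_oligo_full_duplex(self):
        res = self_dimer("ATATATAT", STD)
        assert res.structure == "ATATATAT/TATATATA"
        # hand sum: 4x AT/TA + 3x TA/AT stacks + 2x A/T init + symmetry
        dh = 4 * -7.2 + 3 * -7.2 + 2 * 2.3
        ds = 4 * -20.4 + 3 * -21.3 + 2 * 4.1 - 1.4
        assert res.dH == pytest.approx(dh, abs=1e-9)
        assert res.dS == pytest.approx(ds, abs=1e-9)

    def test_oligo_vs_its_reverse_complement(self):
        seq = "ACGGTCAGTCAA"
        res = cross_dimer(seq, reverse_complement(seq), STD)
        full = duplex_thermo(seq, complement_acgt(seq), STD)
        assert res.dG_at_temp == pytest.approx(full.dG_at_temp, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = random.Random(29)
        for _ in range(30):
            a = random_acgt(rng, rng.randint(8, 16))
            b = random_acgt(rng, rng.randint(8, 16))
            assert cross_dimer(a, b, STD).dG_at_temp == pytest.approx(
                cross_dimer(b, a, STD).dG_at_temp, abs=1e-9
            )

    def test_never_positive(self):
        rng = random.Random(31)
        for _ in range(30):
            seq = random_acgt(rng, rng.randint(6, 20))
            assert self_dimer(seq, STD).dG_at_temp <= 0.0

    def test_windowed_minimum_equals_bruteforce(self):
        """The windowed scan equals exhaustive offset/window enumeration."""
        rng = random.Random(37)
        for _ in range(25):
            a = random_acgt(rng, rng.randint(6, 12))
            b = random_acgt(rng, rng.randint(6, 12))
            assert cross_dimer(a, b, STD).dG_at_temp == pytest.approx(
                brute_force_best_dimer(a, b, STD), abs=1e-9
            )
            assert self_dimer(a, STD).dG_at_temp == pytest.approx(
                brute_force_best_dimer(a, a, STD), abs=1e-9
            )

    def test_degenerate_oligo_uses_most_stable_variant(self):
        degen = Oligo("d_F", "GCGCGCGN", "forward_primer", "s")
        res = self_dimer(degen, STD)
        assert res.variant_indices[0] in range(4)
        # the chosen variant's self-dimer is at least as stable as any other
        from plexscreen.oligos import expand_degenerate

        for variant in expand_degenerate(degen):
            assert res.dG_at_temp <= self_dimer(
                variant.sequence, STD
            ).dG_at_temp + 1e-9


class TestHairpin:
    def test_forced_decomposition(self):
        res = hairpin("GGGGAAAACCCC", STD)
        assert res.structure == "GGGG(AAAA)CCCC"
        assert res.dG_at_temp < 0

    def test_too_short_for_stem_and_loop(self):
        res = hairpin("ACGTACG", STD)
        assert res.is_empty
        assert res.dG_at_temp == 0.0
        assert res.tm is None

    def test_structural_invariants(self):
        rng = random.Random(41)
        found = 0
        for _ in range(200):
            seq = random_acgt(rng, rng.randint(12, 24))
            res = hairpin(seq, STD)
            if res.is_empty:
                continue
            found += 1
            stem5, rest = res.structure.split("(")
            loop, stem3 = rest.split(")")
            stem5 = "".join(c for c in stem5 if c.isupper())
            stem3 = "".join(c for c in stem3 if c.isupper())
            assert len(loop) >= 3
            assert len(stem5) >= 3
            assert stem5 == reverse_complement(stem3)
        assert found > 10  # the invariant actually got exercised

    def test_unimolecular_tm_independent_of_concentration(self):
        tms = {
            hairpin(
                "GGGGAAAACCCC",
                Conditions(annealing_temp=37, monovalent=50, divalent=0,
                           dntp=0, oligo_conc=ct),
            ).tm
            for ct in (10.0, 250.0, 5000.0)
        }
        assert len(tms) == 1

    def test_loop_table_interpolation_and_extrapolation(self):
        loops = default_loop_table()
        # linear interpolation between tabulated sizes
        assert loops.loop_dg37(11) == pytest.approx((4.3 + 4.9) / 2)
        # Jacobson-Stockmayer growth beyond the table
        values = [loops.loop_dg37(n) for n in range(30, 80)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestFlagging:
    def _result(self, dg, tm=None):
        return ThermoResult(-10.0, -30.0, dg, dg, tm, "X/Y")

    def test_cross_dimer_boundary(self):
        conditions = Conditions(annealing_temp=55)
        assert flag_reasons("cross_dimer", self._result(-9.4), conditions)
        assert flag_reasons("cross_dimer", self._result(-9.0), conditions)
        assert not flag_reasons("cross_dimer", self._result(-8.99), conditions)
        assert not flag_reasons("cross_dimer", self._result(-8.7), conditions)

    def test_self_dimer_boundary(self):
        conditions = Conditions(annealing_temp=55)
        assert flag_reasons("self_dimer", self._result(-5.0), conditions)
        assert not flag_reasons("self_dimer", self._result(-4.99), conditions)

    def test_hairpin_dg_or_tm_rule(self):
        conditions = Conditions(annealing_temp=55)
        assert flag_reasons("hairpin", self._result(-5.0), conditions)
        assert not flag_reasons("hairpin", self._result(-1.0, tm=40.0), conditions)
        # 53 + 3 >= 55: flagged by the Tm-proximity rule alone
        assert flag_reasons("hairpin", self._result(-1.0, tm=53.0), conditions)
        assert not flag_reasons("hairpin", self._result(-1.0, tm=51.9), conditions)

    def test_empty_structure_never_flagged(self):
        conditions = Conditions(annealing_temp=55)
        empty = ThermoResult(0, 0, 0, 0, None, "")
        for kind in ("self_dimer", "cross_dimer", "hairpin"):
            assert flag_reasons(kind, empty, conditions) == []


class TestScreenPanel:
    def test_counts_and_flag_structure(self):
        oligos = [
            Oligo("a_F", "GCGCGCGCGCGC", "forward_primer", "s"),
            Oligo("b_R", "ACGTACGTACGT", "reverse_primer", "s"),
            Oligo("c_F", "AAAAAAAAAAAA", "forward_primer", "s"),
        ]
        conditions = Conditions(step="amplification", annealing_temp=55)
        (screen,) = screen_panel(oligos, [conditions])
        n = len(oligos)
        assert len(screen.self_dimers) == n
        assert len(screen.cross_dimers) == n * (n - 1) // 2
        assert len(screen.hairpins) == n
        for flagged in screen.flagged:
            assert flagged.kind in ("self_dimer", "cross_dimer", "hairpin")
            assert flagged.result.dG_at_temp <= 0 or flagged.kind == "hairpin"

    def test_gc_rich_self_complement_is_flagged(self):
        oligos = [Oligo("gc_F", "GCGCGCGCGCGCGCGC", "forward_primer", "s")]
        (screen,) = screen_panel(
            oligos, [Conditions(step="amplification", annealing_temp=55)]
        )
        kinds = {f.kind for f in screen.flagged}
        assert "self_dimer" in kinds


class TestHitDuplex:
    def test_perfect_plus_hit(self):
        res = hit_duplex_thermo("ACGTGCTAGCTAAGGCTT", "ACGTGCTAGCTAAGGCTT", "+", STD)
        assert res is not None and res.dG_at_temp < 0

    def test_minus_hit_equals_plus_of_revcomp(self):
        seq = "ACGTGCTAGCTAAGGCTT"
        plus = hit_duplex_thermo(seq, seq, "+", STD)
        minus = hit_duplex_thermo(seq, reverse_complement(seq), "-", STD)
        assert minus.dH == pytest.approx(plus.dH, abs=1e-9)
        assert minus.dS == pytest.approx(plus.dS, abs=1e-9)

    def test_terminal_mismatch_trimmed(self):
        # reference differs at the oligo's first base -> trimmed core
        res = hit_duplex_thermo("ACGTGCTAGCTAAGGCTT", "TCGTGCTAGCTAAGGCTT", "+", STD)
        assert res is not None

    def test_n_in_reference_unscorable(self):
        assert hit_duplex_thermo("ACGTACGTAC", "ACGTNCGTAC", "+", STD) is None
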