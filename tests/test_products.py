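"""Amplicon prediction: orientation, pairing combinatorics, probe
attachment, unpaired classification, degenerate summary, annotation, and
the product melting temperature."""

import itertools
import random

import pytest

from plexscreen.oligos import MappingRecord, Oligo, ReferenceSeq
from plexscreen.products import (
    annotate_products,
    attach_probes,
    classify_unpaired,
    orient_hits,
    pair_hits,
    product_tm,
    summarize_degenerate,
)
from plexscreen.search import Hit
from plexscreen.thermo import Conditions


def make_hit(name="p_F", role="forward_primer", contig="c1", strand="+",
             start=100, length=20, mm=0, set_id="setA", variant=0):
    return Hit(name, set_id, role, variant, contig, strand, start,
               start + length - 1, mm, "", "A" * length)


class TestOrientHits:
    def test_strand_determines_orientation(self):
        fwd_plus = make_hit("a_F", "forward_primer", strand="+")
        fwd_minus = make_hit("b_F", "forward_primer", strand="-")
        rev_plus = make_hit("c_R", "reverse_primer", strand="+")
        probe = make_hit("d_P", "probe", strand="+")
        rightward, leftward = orient_hits([fwd_plus, fwd_minus, rev_plus, probe])
        assert fwd_plus in rightward and rev_plus in rightward
        assert fwd_minus in leftward
        assert probe not in rightward and probe not in leftward


class TestPairHits:
    def test_basic_pair_and_length(self):
        f = make_hit("f_F", strand="+", start=100)
        r = make_hit("r_R", "reverse_primer", strand="-", start=300)
        products = pair_hits([f, r], 1000)
        assert len(products) == 1
        assert (products[0].start, products[0].end, products[0].length) == (
            100, 319, 220,
        )

    def test_proximity_filter(self):
        f = make_hit("f_F", strand="+", start=100)
        r = make_hit("r_R", "reverse_primer", strand="-", start=300)
        assert pair_hits([f, r], 200) == []

    def test_all_combinations_emitted(self):
        f1 = make_hit("f1_F", strand="+", start=100)
        f2 = make_hit("f2_F", strand="+", start=110)
        r = make_hit("r_R", "reverse_primer", strand="-", start=300)
        products = pair_hits([f1, f2, r], 1000)
        assert len(products) == 2
        assert {p.forward_hit.oligo_name for p in products} == {"f1_F", "f2_F"}

    def test_cross_set_flag(self):
        f = make_hit("f_F", strand="+", start=100, set_id="setA")
        r = make_hit("r_R", "reverse_primer", strand="-", start=200, set_id="setB")
        (product,) = pair_hits([f, r], 1000)
        assert product.cross_set
        assert product.set_id == "setA"

    def test_count_matches_exhaustive_enumeration(self):
        rng = random.Random(3)
        for _ in range(20):
            hits = [
                make_hit(
                    f"h{i}_{'F' if s == '+' else 'R'}",
                    "forward_primer" if s == "+" else "reverse_primer",
                    strand=s,
                    start=rng.randint(1, 2000),
                    length=20,
                )
                for i, s in enumerate(
                    rng.choices("+-", k=rng.randint(2, 30))
                )
            ]
            max_size = rng.choice([100, 500, 1000])
            expected = sum(
                1
                for f, r in itertools.product(hits, hits)
                if f.strand == "+"
                and r.strand == "-"
                and f.start <= r.start
                and r.end - f.start + 1 <= max_size
            )
            assert len(pair_hits(hits, max_size)) == expected


class TestAttachProbes:
    def _product(self):
        f = make_hit("f_F", strand="+", start=100)
        r = make_hit("r_R", "reverse_primer", strand="-", start=300)
        return pair_hits([f, r], 1000)

    def test_containment_attaches_either_strand(self):
        products = self._product()
        inside_plus = make_hit("p1_P", "probe", strand="+", start=150)
        inside_minus = make_hit("p2_P", "probe", strand="-", start=200)
        attach_probes(products, [inside_plus, inside_minus])
        assert len(products[0].probe_hits) == 2

    def test_overhang_excluded(self):
        products = self._product()  # spans [100, 319]
        overhang = make_hit("p_P", "probe", strand="+", start=310)  # ends 329
        attach_probes(products, [overhang])
        assert products[0].probe_hits == []

    def test_wrong_contig_excluded(self):
        products = self._product()
        elsewhere = make_hit("p_P", "probe", contig="c9", start=150)
        attach_probes(products, [elsewhere])
        assert products[0].probe_hits == []


class TestClassifyUnpaired:
    def test_partition(self):
        f = make_hit("f_F", strand="+", start=100)
        r = make_hit("r_R", "reverse_primer", strand="-", start=300)
        lone_plus = make_hit("x_F", strand="+", start=5000)
        lone_minus = make_hit("y_R", "reverse_primer", strand="-", start=10)
        lone_probe = make_hit("z_P", "probe", strand="+", start=7000)
        inside_probe = make_hit("w_P", "probe", strand="+", start=150)
        products = pair_hits([f, r, lone_plus, lone_minus], 1000)
        attach_probes(products, [lone_probe, inside_probe])
        hits = [f, r, lone_plus, lone_minus, lone_probe, inside_probe]
        records = classify_unpaired(hits, products)
        by_name = {rec.hit.oligo_name: rec.category for rec in records}
        assert by_name == {
            "x_F": "forward_without_reverse",
            "y_R": "reverse_without_forward",
            "z_P": "probe_without_product",
        }
        # hits in products never appear among the unpaired
        assert {"f_F", "r_R", "w_P"}.isdisjoint(by_name)


class TestSummarizeDegenerate:
    def test_rows_only_for_degenerate_parents(self):
        degen = Oligo("d_F", "ACGR", "forward_primer", "s")
        plain = Oligo("p_F", "ACGT", "forward_primer", "s")
        hits = [make_hit("d_F", start=100, variant=1)]
        rows = summarize_degenerate([degen, plain], hits)
        assert len(rows) == 1
        row = rows[0]
        assert (row.parent_name, row.n_variants_total) == ("d_F", 2)
        assert (row.n_variants_with_hits, row.n_distinct_placements) == (1, 1)
        assert row.best_mismatch_count == 0

    def test_zero_hit_parent_still_summarized(self):
        degen = Oligo("d_F", "NN", "forward_primer", "s")
        (row,) = summarize_degenerate([degen], [])
        assert row.n_variants_total == 16
        assert row.n_distinct_placements == 0
        assert row.best_mismatch_count is None


class TestAnnotateProducts:
    def _product(self):
        f = make_hit("f_F", strand="+", start=100)
        r = make_hit("r_R", "reverse_primer", strand="-", start=181)  # length 101
        return pair_hits([f, r], 1000)

    def test_size_match_exact(self):
        products = self._product()
        mapping = [MappingRecord("f_F", "blaTEM", 101, ())]
        annotate_products(products, mapping)
        assert products[0].annotation.size_match is True
        assert products[0].annotation.gene_forward == "blaTEM"

    def test_size_match_absent_without_expectation(self):
        products = self._product()
        annotate_products(products, [MappingRecord("f_F", "g", None, ())])
        assert products[0].annotation.size_match is None

    def test_size_mismatch_false_and_tolerance(self):
        products = self._product()
        mapping = [MappingRecord("f_F", "g", 103, ())]
        annotate_products(products, mapping)
        assert products[0].annotation.size_match is False
        annotate_products(products, mapping, size_tolerance=2)
        assert products[0].annotation.size_match is True

    def test_unmapped_oligo_keeps_running(self):
        products = self._product()
        annotate_products(products, [])
        assert products[0].annotation.gene_forward == ""


class TestProductTm:
    CONDITIONS = Conditions(annealing_temp=55, monovalent=50, divalent=0, dntp=0)

    def test_empirical_formula_at_gc50(self):
        # 81.5 + 16.6*log10(0.05) + 0.41*50 - 675/100 = 73.65
        seq = ("AT" * 25) + ("GC" * 25)
        assert product_tm(seq, self.CONDITIONS) == pytest.approx(73.65, abs=5e-3)

    def test_empirical_formula_at_gc0(self):
        assert product_tm("AT" * 50, self.CONDITIONS) == pytest.approx(53.15, abs=5e-3)

    def test_monotone_in_gc(self):
        tms = [
            product_tm("AT" * (50 - g) + "GC" * g, self.CONDITIONS)
            for g in range(0, 51, 10)
        ]
        assert tms == sorted(tms)

    def test_short_product_falls_back_to_nearest_neighbor(self):
        short = "ACGTGCTAGCTAAGGCTTAG"  # 20 bp < 50
        tm = product_tm(short, self.CONDITIONS)
        from plexscreen.thermo import duplex_thermo
        from plexscreen.params import complement_acgt

        expected = duplex_thermo(short, complement_acgt(short), self.CONDITIONS).tm
        assert tm == pytest.approx(expected)

    def test_n_yields_none_and_empty_is_fatal(self):
        assert product_tm("ACGTN" * 20, self.CONDITIONS) is None
        with pytest.raises(Exception):
            product_tm("", self.CONDITIONS)
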