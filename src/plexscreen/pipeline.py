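"""Single-command pipeline: search -> pairing -> probes -> summaries ->
annotation -> thermodynamics, with byte-stable CSV outputs.

All output rows are deterministically sorted and floats are printed with
two decimals (kcal/mol and degrees C), so identical configurations yield
byte-identical output bundles.  ``run.log`` carries per-stage counts and
deliberately no timestamps.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, asdict

from .errors import InputFormatError, PlexScreenError
from .oligos import (
    ROLE_PROBE,
    MappingRecord,
    Oligo,
    ReferenceSeq,
    expand_degenerate,
    load_mapping_csv,
    load_oligo_sets,
    load_references,
)
from .products import (
    DegenerateSummary,
    Product,
    UnpairedRecord,
    annotate_products,
    attach_probes,
    classify_unpaired,
    pair_hits,
    product_tm,
    summarize_degenerate,
)
from .search import Hit, SearchConfig, deduplicate_hits, search_references
from .thermo import (
    STEP_AMPLIFICATION,
    STEP_HYBRIDIZATION,
    Conditions,
    ScreenThresholds,
    StepScreen,
    hit_duplex_thermo,
    screen_panel,
)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; echoed verbatim to disk."""

    references: list[str] = field(default_factory=list)
    primers: list[str] = field(default_factory=list)
    probes: list[str] = field(default_factory=list)
    mapping: str | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    max_product_size: int = 1000
    amplification: Conditions = field(
        default_factory=lambda: Conditions(step=STEP_AMPLIFICATION)
    )
    hybridization: Conditions = field(
        default_factory=lambda: Conditions(step=STEP_HYBRIDIZATION, annealing_temp=45.0)
    )
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    size_tolerance: int = 0
    forward_suffix: str = "_F"
    reverse_suffix: str = "_R"
    probe_file_suffix: str = "_probes"
    out_dir: str = "plexscreen_out"

    def validate(self) -> None:
        if self.max_product_size <= 0:
            raise PlexScreenError("max_product_size must be > 0")
        if not self.references:
            raise InputFormatError("no reference files given")
        if not self.primers:
            raise InputFormatError("no primer files given")
        for path in [*self.references, *self.primers, *self.probes] + (
            [self.mapping] if self.mapping else []
        ):
            if not os.path.exists(path):
                raise InputFormatError(f"input file not found: {path}")


@dataclass
class PipelineResult:
    references: list[ReferenceSeq]
    oligos: list[Oligo]
    raw_hits: list[Hit]
    hits: list[Hit]  # deduplicated
    products: list[Product]
    unpaired: list[UnpairedRecord]
    degenerate: list[DegenerateSummary]
    screens: list[StepScreen]
    log_lines: list[str]


def _fmt(value, decimals: int = 2) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.{decimals}f}"
    return str(value)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute all stages in order and (optionally) write the output bundle."""
    config.validate()
    log: list[str] = []

    references = load_references(config.references)
    refs_by_id = {r.contig_id: r for r in references}
    log.append(f"references: {len(references)} contigs, "
               f"{sum(len(r.sequence) for r in references)} bp")

    oligos = load_oligo_sets(
        config.primers,
        config.probes,
        forward_suffix=config.forward_suffix,
        reverse_suffix=config.reverse_suffix,
        probe_file_suffix=config.probe_file_suffix,
    )
    variant_seqs = {o.name: [v.sequence for v in expand_degenerate(o)] for o in oligos}
    n_variants = sum(len(v) for v in variant_seqs.values())
    log.append(f"oligos: {len(oligos)} ({n_variants} expanded variants)")

    raw_hits = search_references(oligos, references, config.search)
    log.append(f"raw hits: {len(raw_hits)}")
    hits = deduplicate_hits(raw_hits)
    log.append(f"hits after deduplication: {len(hits)}")

    primer_hits = [h for h in hits if h.role != ROLE_PROBE]
    probe_hits = [h for h in hits if h.role == ROLE_PROBE]
    products = pair_hits(primer_hits, config.max_product_size, refs_by_id)
    attach_probes(products, probe_hits)
    log.append(f"products: {len(products)}")

    unpaired = classify_unpaired(hits, products)
    log.append(f"unpaired hits: {len(unpaired)}")
    degenerate = summarize_degenerate(oligos, hits)
    log.append(f"degenerate parents summarized: {len(degenerate)}")

    mapping: list[MappingRecord] = []
    if config.mapping:
        mapping = load_mapping_csv(config.mapping)
    annotate_products(products, mapping, size_tolerance=config.size_tolerance)

    for product in products:
        product.product_tm = (
            product_tm(product.sequence, config.amplification)
            if product.sequence
            else None
        )
        for attr, hit in (
            ("forward_thermo", product.forward_hit),
            ("reverse_thermo", product.reverse_hit),
        ):
            seq = variant_seqs[hit.oligo_name][hit.variant_index]
            setattr(
                product,
                attr,
                hit_duplex_thermo(
                    seq, hit.matched_ref_seq, hit.strand, config.amplification
                ),
            )
        product.probe_thermos = [
            hit_duplex_thermo(
                variant_seqs[p.oligo_name][p.variant_index],
                p.matched_ref_seq,
                p.strand,
                config.hybridization,
            )
            for p in product.probe_hits
        ]

    screens = screen_panel(
        oligos, [config.amplification, config.hybridization], config.thresholds
    )
    log.append(
        "flagged structures: "
        + str(sum(len(screen.flagged) for screen in screens))
    )

    result = PipelineResult(
        references, oligos, raw_hits, hits, products, unpaired, degenerate,
        screens, log,
    )
    if write_outputs:
        write_output_bundle(result, config)
    return result


# ---------------------------------------------------------------------------
# writers


def _writer(path):
    handle = open(path, "w", newline="")
    return handle, csv.writer(handle)


def write_hits_csv(path, hits: list[Hit]) -> None:
    handle, writer = _writer(path)
    with handle:
        writer.writerow([
            "oligo_name", "set_id", "role", "contig_id", "strand",
            "start", "end", "mismatches", "mismatch_repr", "matched_ref_seq",
        ])
        for h in hits:
            writer.writerow([
                h.oligo_name, h.set_id, h.role, h.contig_id, h.strand,
                h.start, h.end, h.mismatches, h.mismatch_repr, h.matched_ref_seq,
            ])


def write_products_csv(path, products: list[Product]) -> None:
    """Long format: one row per product-probe combination."""
    handle, writer = _writer(path)
    with handle:
        writer.writerow([
            "contig_id", "start", "end", "length", "set_id", "cross_set",
            "fwd_name", "fwd_start", "fwd_end", "fwd_mismatches",
            "fwd_mismatch_repr", "fwd_dg", "fwd_tm",
            "rev_name", "rev_start", "rev_end", "rev_mismatches",
            "rev_mismatch_repr", "rev_dg", "rev_tm",
            "probe_name", "probe_strand", "probe_start", "probe_end",
            "probe_mismatches", "probe_mismatch_repr", "probe_dg", "probe_tm",
            "product_tm", "gene_forward", "gene_reverse", "gene_probe",
            "expected_size", "size_match", "extra_info", "product_sequence",
        ])
        for p in products:
            ann = p.annotation
            expected = ""
            if ann and ann.expected_size_forward is not None:
                expected = str(ann.expected_size_forward)
            elif ann and ann.expected_size_reverse is not None:
                expected = str(ann.expected_size_reverse)
            extras = ""
            if ann and ann.extras:
                extras = "|".join(
                    f"{name}:{';'.join(f'{k}={v}' for k, v in fields)}"
                    for name, fields in ann.extras
                )
            base = [
                p.contig_id, p.start, p.end, p.length, p.set_id,
                _fmt(p.cross_set),
                p.forward_hit.oligo_name, p.forward_hit.start,
                p.forward_hit.end, p.forward_hit.mismatches,
                p.forward_hit.mismatch_repr,
                _fmt(p.forward_thermo.dG_at_temp if p.forward_thermo else None),
                _fmt(p.forward_thermo.tm if p.forward_thermo else None),
                p.reverse_hit.oligo_name, p.reverse_hit.start,
                p.reverse_hit.end, p.reverse_hit.mismatches,
                p.reverse_hit.mismatch_repr,
                _fmt(p.reverse_thermo.dG_at_temp if p.reverse_thermo else None),
                _fmt(p.reverse_thermo.tm if p.reverse_thermo else None),
            ]
            tail = [
                _fmt(p.product_tm),
                ann.gene_forward if ann else "",
                ann.gene_reverse if ann else "",
                "",  # gene_probe placeholder, overwritten per probe row
                expected,
                _fmt(ann.size_match) if ann and ann.size_match is not None else "",
                extras,
                p.sequence,
            ]
            probe_gene = dict(ann.probe_genes) if ann else {}
            if p.probe_hits:
                for probe, thermo in zip(p.probe_hits, p.probe_thermos):
                    row = list(base)
                    row += [
                        probe.oligo_name, probe.strand, probe.start, probe.end,
                        probe.mismatches, probe.mismatch_repr,
                        _fmt(thermo.dG_at_temp if thermo else None),
                        _fmt(thermo.tm if thermo else None),
                    ]
                    row += tail
                    row[-5] = probe_gene.get(probe.oligo_name, "")
                    writer.writerow(row)
            else:
                writer.writerow(base + [""] * 8 + tail)


def write_unpaired_csv(path, unpaired: list[UnpairedRecord]) -> None:
    handle, writer = _writer(path)
    with handle:
        writer.writerow([
            "category", "oligo_name", "set_id", "role", "contig_id",
            "strand", "start", "end", "mismatches", "mismatch_repr",
        ])
        for rec in unpaired:
            h = rec.hit
            writer.writerow([
                rec.category, h.oligo_name, h.set_id, h.role, h.contig_id,
                h.strand, h.start, h.end, h.mismatches, h.mismatch_repr,
            ])


def write_degenerate_csv(path, rows: list[DegenerateSummary]) -> None:
    handle, writer = _writer(path)
    with handle:
        writer.writerow([
            "parent_name", "n_variants_total", "n_variants_with_hits",
            "n_distinct_placements", "best_mismatch_count",
        ])
        for r in rows:
            writer.writerow([
                r.parent_name, r.n_variants_total, r.n_variants_with_hits,
                r.n_distinct_placements,
                "" if r.best_mismatch_count is None else r.best_mismatch_count,
            ])


def write_dimer_outputs(out_dir, screens: list[StepScreen], oligos: list[Oligo]) -> None:
    names = [o.name for o in oligos]
    handle, writer = _writer(os.path.join(out_dir, "dimers_matrix.csv"))
    with handle:
        writer.writerow(["step", "oligo"] + names)
        for screen in screens:
            for n1 in names:
                row = [screen.conditions.step, n1]
                for n2 in names:
                    if n1 == n2:
                        res = screen.self_dimers[n1]
                    else:
                        res = screen.cross_dimers.get(
                            (n1, n2)
                        ) or screen.cross_dimers.get((n2, n1))
                    row.append(_fmt(res.dG_at_temp))
                writer.writerow(row)
    handle, writer = _writer(os.path.join(out_dir, "dimers_flagged.csv"))
    with handle:
        writer.writerow([
            "step", "kind", "oligo1", "oligo2", "variant1", "variant2",
            "dH", "dS", "dG", "dG37", "tm", "structure", "reason",
        ])
        for screen in screens:
            for f in screen.flagged:
                if f.kind == "hairpin":
                    continue
                v = f.result.variant_indices
                writer.writerow([
                    f.step, f.kind, f.oligo1, f.oligo2 or "",
                    v[0] if v else "", v[1] if len(v) > 1 else "",
                    _fmt(f.result.dH), _fmt(f.result.dS),
                    _fmt(f.result.dG_at_temp), _fmt(f.result.dG37),
                    _fmt(f.result.tm), f.result.structure, f.reason,
                ])
    handle, writer = _writer(os.path.join(out_dir, "hairpins.csv"))
    with handle:
        writer.writerow([
            "step", "oligo", "variant", "dH", "dS", "dG", "dG37", "tm",
            "structure", "flagged", "reason",
        ])
        for screen in screens:
            flagged_hairpins = {
                f.oligo1: f.reason for f in screen.flagged if f.kind == "hairpin"
            }
            for name in names:
                res = screen.hairpins[name]
                v = res.variant_indices
                writer.writerow([
                    screen.conditions.step, name, v[0] if v else "",
                    _fmt(res.dH), _fmt(res.dS), _fmt(res.dG_at_temp),
                    _fmt(res.dG37), _fmt(res.tm), res.structure,
                    _fmt(name in flagged_hairpins),
                    flagged_hairpins.get(name, ""),
                ])


def _echo_config(config: RunConfig) -> list[str]:
    lines: list[str] = []

    def flatten(prefix: str, value) -> None:
        if isinstance(value, dict):
            for key in sorted(value):
                flatten(f"{prefix}.{key}" if prefix else str(key), value[key])
        elif isinstance(value, (list, tuple)):
            lines.append(f"{prefix} = {','.join(str(v) for v in value)}")
        else:
            lines.append(f"{prefix} = {value}")

    flatten("", asdict(config))
    return lines


def write_output_bundle(result: PipelineResult, config: RunConfig) -> None:
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    write_hits_csv(os.path.join(out_dir, "hits.csv"), result.hits)
    write_products_csv(os.path.join(out_dir, "products.csv"), result.products)
    write_unpaired_csv(os.path.join(out_dir, "unpaired.csv"), result.unpaired)
    write_degenerate_csv(
        os.path.join(out_dir, "degenerate_summary.csv"), result.degenerate
    )
    write_dimer_outputs(out_dir, result.screens, result.oligos)
    with open(os.path.join(out_dir, "run.log"), "w") as handle:
        handle.write("\n".join(result.log_lines) + "\n")
    with open(os.path.join(out_dir, "config.echo"), "w") as handle:
        handle.write("\n".join(_echo_config(config)) + "\n")
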