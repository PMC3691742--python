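"""End-to-end orchestration of the analysis stages from a single config.

Stages run in dependency order: annotation analytics and codon usage need
only genome+annotation; divergence needs a second genome; expression, poly(A)
and SNP stages need reads (FASTQ, mapped internally) or precomputed
alignments (SAM/BAM or the internal TSV); cistron prediction needs the
annotation and optionally contigs; control-region analysis needs the genome.
All outputs are plain TSV/VCF/bedGraph files plus a short text summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import expression as expr_mod
from .genome_model import (
    MitoGenome,
    CONTROL_REGION,
    extract_feature_sequence,
    feature_length,
    intergenic_spacers,
    overlaps,
    parse_annotation,
    read_fasta,
)
from .mito_code import INVERTEBRATE_MITO, codon_usage
from .divergence import align_orthologs, ka_ks, partition_divergence, skew
from .mapper import map_reads
from .polya import assign_polya_events, detect_tail_reads, find_polya_signals, read_fastq
from .cistrons import place_contigs, predict_units
from .variants import annotate_variant, build_pileup, call_snps, write_variant_table, write_vcf
from .control_region import find_stem_loops, find_tandem_repeats, scan_motifs

ALL_STAGES = ("annotate", "codon", "divergence", "expression", "polya", "cistrons", "snps", "control-region")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for one pipeline run."""

    outdir: str
    genome: str | None = None
    annotation: str | None = None
    genome_length: int | None = None
    reads: str | None = None
    alignments: str | None = None
    contigs: str | None = None
    genome_b: str | None = None
    annotation_b: str | None = None
    stages: tuple[str, ...] = ()
    seed: int = 0
    min_tail: int = 9
    min_depth: int = 10
    min_alt_frac: float = 0.2
    min_spacer: int = 10
    max_gap: int = 50
    max_mismatches: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["stages"] = tuple(raw.get("stages", ()))
        return cls(**raw)


def _validate(config: PipelineConfig) -> None:
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    needs_genome = set(config.stages) & {"annotate", "codon", "divergence", "expression",
                                         "polya", "snps", "control-region", "cistrons"}
    if needs_genome and config.annotation is None:
        raise ValueError("enabled stages require an annotation")
    if set(config.stages) & {"codon", "divergence", "polya", "snps", "control-region"} and config.genome is None:
        raise ValueError("enabled stages require a genome FASTA")
    if "divergence" in config.stages and (config.genome_b is None or config.annotation_b is None):
        raise ValueError("divergence stage requires genome_b and annotation_b")
    if set(config.stages) & {"expression", "polya", "snps"} and config.reads is None and config.alignments is None:
        raise ValueError("expression/polya/snps stages require reads or alignments")
    for name in ("genome", "annotation", "reads", "alignments", "contigs", "genome_b", "annotation_b"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise ValueError(f"{name} file not found: {p}")


def _load_alignments(config: PipelineConfig, genome: MitoGenome):
    if config.alignments:
        path = Path(config.alignments)
        if path.suffix.lower() in {".sam", ".bam"}:
            return expr_mod.read_sam(path)
        return expr_mod.read_alignments_tsv(path)
    reads = read_fastq(config.reads)
    alns, _ = map_reads(reads, genome, max_mismatches=config.max_mismatches)
    return alns


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a summary dict (also written out)."""
    _validate(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": list(config.stages)}
    if not config.stages:
        (out / "summary.txt").write_text("no stages enabled\n")
        return summary

    genome = read_fasta(config.genome) if config.genome else None
    L = config.genome_length or (genome.length if genome else None)
    table = parse_annotation(config.annotation, L) if config.annotation else None
    code = INVERTEBRATE_MITO
    alns = None

    if "annotate" in config.stages:
        with open(out / "annotation_stats.tsv", "w") as fh:
            fh.write("record\tname\tvalue\n")
            for f in table.features:
                fh.write(f"length\t{f.name}\t{feature_length(f, L)}\n")
            for a, b, n in overlaps(table):
                fh.write(f"overlap\t{a}|{b}\t{n}\n")
            spacers = intergenic_spacers(table, min_len=config.min_spacer)
            for sp in spacers:
                fh.write(f"spacer\t{sp.flanking[0]}|{sp.flanking[1]}\t{sp.length}\n")
        summary["n_features"] = len(table)
        summary["n_spacers"] = len(spacers)

    if "codon" in config.stages:
        cds = [extract_feature_sequence(genome, f) for f in table.pcgs]
        usage = codon_usage(cds, code)
        usage.to_dataframe(code).to_csv(out / "codon_usage.tsv", sep="\t", index=False)
        sk = skew(genome.seq)
        summary["at_skew"] = sk.at_skew
        summary["gc_skew"] = sk.gc_skew

    if "divergence" in config.stages:
        genome_b = read_fasta(config.genome_b)
        table_b = parse_annotation(config.annotation_b, genome_b.length)
        pairs = []
        rows = []
        for f in table.pcgs:
            try:
                fb = table_b.get(f.name)
            except KeyError:
                continue
            pair = align_orthologs(
                extract_feature_sequence(genome, f), extract_feature_sequence(genome_b, fb), code, gene=f.name
            )
            pairs.append(pair)
            r = ka_ks(pair, code)
            rows.append((f.name, r.ka, r.ks, r.ratio))
        with open(out / "ka_ks.tsv", "w") as fh:
            fh.write("gene\tka\tks\tka_ks\n")
            for name, ka, ks, ratio in rows:
                fh.write(f"{name}\t{_fmt(ka)}\t{_fmt(ks)}\t{_fmt(ratio)}\n")
        partition_divergence(pairs, code).to_dataframe().to_csv(
            out / "divergence_partition.tsv", sep="\t", index=False
        )
        summary["n_ortholog_pairs"] = len(pairs)

    if set(config.stages) & {"expression", "polya", "snps"}:
        alns = _load_alignments(config, genome)
        summary["n_alignments"] = len(alns)

    if "expression" in config.stages:
        depth = expr_mod.compute_depth(alns, L)
        expr_mod.write_bedgraph(depth, out / "depth.bedgraph", chrom=genome.seq.id if genome else "mitogenome")
        records = expr_mod.expression_levels(alns, table, min_spacer=config.min_spacer)
        with open(out / "expression.tsv", "w") as fh:
            fh.write("name\tcategory\tmapped_reads\tlength\treads_per_base\n")
            for r in records:
                fh.write(f"{r.name}\t{r.category}\t{r.mapped_reads}\t{r.length}\t{r.level:.4f}\n")
        summary["top_expressed"] = records[0].name if records else None

    if "polya" in config.stages:
        if config.reads is None:
            raise ValueError("polya stage requires FASTQ reads")
        tails = detect_tail_reads(read_fastq(config.reads), min_tail=config.min_tail)
        events, dropped = assign_polya_events(tails, genome, table)
        with open(out / "polya_events.tsv", "w") as fh:
            fh.write("read_id\tgene\tjunction\tstrand\ttail_len\toffset_from_stop\tcompleted_stop\n")
            for e in events:
                fh.write(f"{e.read_id}\t{e.gene}\t{e.junction}\t{e.strand}\t{e.tail_len}\t"
                         f"{e.offset_from_stop}\t{e.completed_stop or ''}\n")
        seen = {}
        for e in events:
            seen.setdefault((e.gene, e.junction, e.strand), e)
        with open(out / "polya_signals.tsv", "w") as fh:
            fh.write("gene\tjunction\tmotif\tposition\tdistance_upstream\n")
            for (gene_name, junction, strand), e in sorted(seen.items()):
                for sig in find_polya_signals(genome, e):
                    fh.write(f"{gene_name}\t{junction}\t{sig.motif}\t{sig.position}\t{sig.distance_upstream}\n")
        summary["n_polya_events"] = len(events)
        summary["polya_dropped"] = dict(dropped)

    if "cistrons" in config.stages:
        units = predict_units(table, max_gap=config.max_gap)
        with open(out / "transcription_units.tsv", "w") as fh:
            fh.write("unit\tstrand\tcistron_count\tmembers\n")
            for u in units:
                fh.write(f"{u.unit_id}\t{u.strand}\t{u.cistron_count}\t{','.join(u.members)}\n")
        summary["n_units"] = len(units)
        summary["n_dicistronic"] = sum(1 for u in units if u.cistron_count == 2)
        if config.contigs and genome is not None:
            placements = place_contigs(config.contigs, genome, table)
            with open(out / "contig_placements.tsv", "w") as fh:
                fh.write("contig\tstart\tend\tstrand\tidentity\tlength\tgenes_contained\tgenes_partial\n")
                for p in placements:
                    fh.write(f"{p.contig_id}\t{p.start or ''}\t{p.end or ''}\t{p.strand or ''}\t"
                             f"{p.identity:.3f}\t{p.length}\t{','.join(p.genes_contained)}\t"
                             f"{','.join(p.genes_partial)}\n")

    if "snps" in config.stages:
        pileup = build_pileup(alns, genome)
        calls = [
            annotate_variant(pos, ref, alt, genome, table, code, depth=dp, alt_frac=frac)
            for pos, ref, alt, dp, frac in call_snps(pileup, config.min_depth, config.min_alt_frac)
        ]
        write_variant_table(calls, out / "snps.tsv")
        write_vcf(calls, genome, out / "snps.vcf")
        summary["n_snps"] = len(calls)

    if "control-region" in config.stages:
        with open(out / "control_regions.tsv", "w") as fh:
            fh.write("region\trecord\tdetail\n")
            for f in table.by_category(CONTROL_REGION):
                seq = extract_feature_sequence(genome, f).bases
                for rep in find_tandem_repeats(seq):
                    fh.write(f"{f.name}\trepeat\tstart={f.start + rep.start - 1};unit={rep.unit_length};"
                             f"copies={rep.copy_number:.2f}\n")
                for hit in scan_motifs(seq):
                    fh.write(f"{f.name}\tmotif\t{hit.motif}@{f.start + hit.position - 1}\n")
                for sl in find_stem_loops(seq):
                    fh.write(f"{f.name}\tstem_loop\tstem={sl.stem_length};loop={sl.loop_length};"
                             f"at={f.start + sl.span[0] - 1}\n")

    lines = [f"{k}: {v}" for k, v in summary.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary


def _fmt(x) -> str:
    return "" if x is None else f"{x:.4f}"
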