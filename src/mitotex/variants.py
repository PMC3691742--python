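"""Pileup construction, depth-filtered SNP calling, and functional annotation.

Calls follow the study design: a site is callable at depth >= 10 (default)
and the top non-reference base must reach a minimum fraction (our addition,
default 0.2, to suppress sequencing-error calls).  Annotation translates the
affected codon under the invertebrate mitochondrial code, complementing
alleles onto the reading strand for minus-strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_model import (
    AnnotationTable,
    MitoGenome,
    PCG,
    CONTROL_REGION,
    extract_feature_sequence,
    locate_position,
    position_in_feature,
)
from .mito_code import GeneticCode, INVERTEBRATE_MITO
from .expression import ReadAlignment

__all__ = [
    "PileupColumn",
    "build_pileup",
    "call_snps",
    "VariantCall",
    "annotate_variant",
    "write_vcf",
    "write_variant_table",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PileupColumn:
    """Plus-strand base counts at one covered genome position."""

    position: int
    ref: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def build_pileup(alignments: list[ReadAlignment], genome: MitoGenome) -> list[PileupColumn]:
    """Per-position plus-strand base counts from ungapped alignments.

    Alignment sequences must already be plus-strand oriented (the internal
    mapper stores them that way; minus-strand SAM records come back oriented
    from pysam).  Positions with no coverage are absent from the output.
    """
    L = genome.length
    acc: dict[int, dict[str, int]] = {}
    for a in alignments:
        if a.seq is None:
            raise ValueError(f"alignment {a.read_id} carries no sequence")
        if len(a.seq) != a.length:
            raise ValueError(f"alignment {a.read_id}: sequence/length mismatch")
        for i, base in enumerate(a.seq):
            if base not in _BASES:
                continue
            pos = (a.start - 1 + i) % L + 1
            acc.setdefault(pos, {b: 0 for b in _BASES})[base] += 1
    return [
        PileupColumn(position=pos, ref=genome.base(pos), counts=counts)
        for pos, counts in sorted(acc.items())
    ]


def call_snps(
    pileup: list[PileupColumn],
    min_depth: int = 10,
    min_alt_frac: float = 0.2,
) -> list[tuple[int, str, str, int, float]]:
    """Depth- and fraction-filtered SNP calls: (pos, ref, alt, depth, frac)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    calls = []
    for col in pileup:
        depth = col.depth
        if depth < min_depth:
            continue
        alts = [(n, b) for b, n in col.counts.items() if b != col.ref and n > 0]
        if not alts:
            continue
        n, alt = max(alts)
        frac = n / depth
        if frac >= min_alt_frac:
            calls.append((col.position, col.ref, alt, depth, frac))
    return calls


@dataclass(frozen=True)
class VariantCall:
    """A fully annotated SNP (plus-strand alleles; codons on reading strand)."""

    position: int
    ref: str
    alt: str
    gene: str
    strand: str | None
    position_in_gene: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    effect: str  # synonymous | missense | noncoding
    depth: int | None = None
    alt_frac: float | None = None


def annotate_variant(
    pos: int,
    ref: str,
    alt: str,
    genome: MitoGenome,
    table: AnnotationTable,
    code: GeneticCode = INVERTEBRATE_MITO,
    depth: int | None = None,
    alt_frac: float | None = None,
) -> VariantCall:
    """Annotate a plus-strand SNP with its gene, codon and amino-acid change.

    For minus-strand genes the alleles are complemented onto the reading
    strand before codon lookup.  Positions in control regions annotate as
    'CR region'; tRNA/rRNA positions keep the gene name; unannotated
    positions report 'intergenic'.  All noncoding calls omit codon fields.
    """
    ref, alt = ref.upper(), alt.upper()
    if genome.base(pos) != ref:
        raise ValueError(f"reference mismatch at {pos}: genome has {genome.base(pos)}, got {ref}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    hits = locate_position(pos, table)
    pcgs = [f for f in hits if f.category == PCG]
    if pcgs:
        f = pcgs[0]
        pig = position_in_feature(pos, f, table.genome_length)
        codon_idx = (pig - 1) // 3
        within = (pig - 1) % 3
        gene_seq = extract_feature_sequence(genome, f).bases
        codon = gene_seq[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon) < 3:
            # inside a trailing partial stop codon: no complete codon to assess
            return VariantCall(pos, ref, alt, f.name, f.strand, pig, None, None, None, None,
                               "noncoding", depth, alt_frac)
        r_ref = ref if f.strand == "+" else ref.translate(_COMP)
        r_alt = alt if f.strand == "+" else alt.translate(_COMP)
        assert codon[within] == r_ref
        alt_codon = codon[:within] + r_alt + codon[within + 1 :]
        ref_aa, alt_aa = code.aa(codon), code.aa(alt_codon)
        effect = "synonymous" if ref_aa == alt_aa else "missense"
        return VariantCall(pos, ref, alt, f.name, f.strand, pig, codon, alt_codon,
                           ref_aa, alt_aa, effect, depth, alt_frac)
    crs = [f for f in hits if f.category == CONTROL_REGION]
    if crs:
        return VariantCall(pos, ref, alt, "CR region", None, None, None, None, None, None,
                           "noncoding", depth, alt_frac)
    if hits:
        f = hits[0]
        pig = position_in_feature(pos, f, table.genome_length)
        return VariantCall(pos, ref, alt, f.name, f.strand, pig, None, None, None, None,
                           "noncoding", depth, alt_frac)
    return VariantCall(pos, ref, alt, "intergenic", None, None, None, None, None, None,
                       "noncoding", depth, alt_frac)


def write_variant_table(calls: list[VariantCall], path: str | Path) -> None:
    """TSV mirroring the classic SNP-table layout."""
    with open(path, "w") as fh:
        fh.write("Pos\tRef\tAlt\tGene_name\tStrand\tSNP_position_in_gene\t"
                 "Three_base_ref\tThree_base_alt\taa_ref\taa_alt\tEffect\tDepth\tAltFrac\n")
        for c in calls:
            fh.write("\t".join([
                str(c.position), c.ref, c.alt, c.gene, c.strand or "",
                str(c.position_in_gene or ""), c.ref_codon or "", c.alt_codon or "",
                c.ref_aa or "", c.alt_aa or "", c.effect,
                str(c.depth if c.depth is not None else ""),
                f"{c.alt_frac:.3f}" if c.alt_frac is not None else "",
            ]) + "\n")


def write_vcf(calls: list[VariantCall], genome: MitoGenome, path: str | Path) -> None:
    """Minimal VCF v4.2 with gene/effect annotations in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.seq.id},length={genome.length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene context">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = [f"GENE={c.gene.replace(' ', '_')}", f"EFFECT={c.effect}"]
            if c.depth is not None:
                info.append(f"DP={c.depth}")
            fh.write(f"{genome.seq.id}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{';'.join(info)}\n")
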