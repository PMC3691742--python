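"""Circular mitogenome data model: sequence, annotation, coordinate arithmetic, I/O.

Coordinates are 1-based and fully inclusive throughout, matching the convention
of published insect mitogenome annotation tables.  The genome is circular by
default; at most one feature may wrap the origin (``wraps_origin``), and all
position arithmetic is modulo the genome length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
__all__ = [
    "NucleotideSequence",
    "MitoGenome",
    "GeneFeature",
    "AnnotationTable",
    "SpacerRegion",
    "PCG",
    "TRNA",
    "RRNA",
    "CONTROL_REGION",
    "reverse_complement",
    "parse_annotation",
    "read_fasta",
    "write_fasta",
    "feature_length",
    "extract_feature_sequence",
    "position_in_feature",
    "locate_position",
    "intergenic_spacers",
    "overlaps",
]

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"

_CATEGORIES = {PCG, TRNA, RRNA, CONTROL_REGION}
_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PARTIAL_STOPS = {"T", "TA"}
COMPLETE_STOPS = {"TAA", "TAG"}
ALLOWED_STOPS = PARTIAL_STOPS | COMPLETE_STOPS


def reverse_complement(bases: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T,N}; lowercase input is normalized."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(bases) - _ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters {sorted(bad)}")
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.bases))


@dataclass(frozen=True)
class MitoGenome:
    """A (by default circular) mitochondrial genome sequence."""

    seq: NucleotideSequence
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (mod length when circular)."""
        L = self.length
        if self.circular:
            pos = (pos - 1) % L + 1
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} outside genome of length {L}")
        return self.seq.bases[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Plus-strand bases from ``start`` to ``end`` inclusive.

        ``end < start`` denotes a span wrapping the origin (circular only).
        """
        L = self.length
        if not (1 <= start <= L and 1 <= end <= L):
            raise ValueError(f"span {start}..{end} outside genome of length {L}")
        if start <= end:
            return self.seq.bases[start - 1 : end]
        if not self.circular:
            raise ValueError("wrap-around span on a linear genome")
        return self.seq.bases[start - 1 :] + self.seq.bases[:end]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene/region: 1-based inclusive coordinates on a strand."""

    name: str
    category: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(f"{self.name}: start > end without wraps_origin")
        if self.category == PCG and self.stop_codon is not None and self.stop_codon not in ALLOWED_STOPS:
            raise ValueError(f"{self.name}: stop codon {self.stop_codon!r} not in {sorted(ALLOWED_STOPS)}")

    def contains(self, pos: int, L: int | None = None) -> bool:
        if not self.wraps_origin:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


def feature_length(f: GeneFeature, L: int | None = None) -> int:
    """Feature length in bp (inclusive coordinates; mod-L for origin wrap)."""
    if not f.wraps_origin:
        return f.end - f.start + 1
    if L is None:
        raise ValueError("genome length required for a wrapping feature")
    return (f.end - f.start) % L + 1


def infer_category(name: str) -> str:
    low = name.lower()
    if low.startswith("trna"):
        return TRNA
    if low.startswith("rrn"):
        return RRNA
    if low.startswith("cr") or "control" in low:
        return CONTROL_REGION
    return PCG


@dataclass
class AnnotationTable:
    """Ordered annotation of a single circular mitogenome."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dup}")
        wrapping = [f for f in self.features if f.wraps_origin]
        if len(wrapping) > 1:
            raise ValueError("at most one feature may wrap the origin")
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise ValueError(
                    f"{f.name}: coordinates {f.start}..{f.end} exceed genome length {self.genome_length}"
                )
        self.features.sort(key=lambda f: (f.start, f.end))

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, *categories: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category in categories]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.by_category(PCG)

    @property
    def genes(self) -> list[GeneFeature]:
        """All features except control regions (the classic 37-gene set)."""
        return [f for f in self.features if f.category != CONTROL_REGION]

    def to_tsv(self, path: str | Path | io.TextIOBase | None = None) -> str:
        """Serialize as a Gene/Strand/From/To/Length/Start/Stop table."""
        lines = ["Gene\tStrand\tFrom\tTo\tLength\tStart\tStop"]
        for f in self.features:
            lines.append(
                "\t".join(
                    [
                        f.name,
                        f.strand,
                        str(f.start),
                        str(f.end),
                        str(feature_length(f, self.genome_length)),
                        f.start_codon or "",
                        f.stop_codon or "",
                    ]
                ).rstrip("\t")
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            if isinstance(path, (str, Path)):
                Path(path).write_text(text)
            else:
                path.write(text)
        return text

    def to_gff3(self, path: str | Path | None = None, seqid: str = "mitogenome") -> str:
        """GFF3 export (1-based inclusive coordinates, native to GFF3)."""
        types = {PCG: "gene", TRNA: "tRNA", RRNA: "rRNA", CONTROL_REGION: "region"}
        lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {self.genome_length}"]
        for f in self.features:
            attrs = [f"ID={f.name}", f"Name={f.name}", f"category={f.category}"]
            if f.start_codon:
                attrs.append(f"start_codon={f.start_codon}")
            if f.stop_codon:
                attrs.append(f"stop_codon={f.stop_codon}")
            lines.append(
                "\t".join(
                    [
                        seqid,
                        "mitotex",
                        types[f.category],
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


_STRAND_ALIASES = {"+": "+", "-": "-", "_": "-", "−": "-", ".": "+"}


def _parse_table_tsv(text: str, genome_length: int) -> AnnotationTable:
    features: list[GeneFeature] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty annotation file")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    required = {"gene", "strand", "from", "to"}
    if not required <= set(header):
        raise ValueError(f"annotation header missing columns {sorted(required - set(header))}")
    idx = {name: header.index(name) for name in header}
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")

        def col(name: str) -> str:
            i = idx.get(name)
            if i is None or i >= len(cols):
                return ""
            return cols[i].strip()

        name = col("gene")
        if not name:
            raise ValueError(f"line {lineno}: missing gene name")
        strand = _STRAND_ALIASES.get(col("strand"))
        if strand is None:
            raise ValueError(f"line {lineno}: bad strand {col('strand')!r}")
        try:
            start = int(col("from"))
            end = int(col("to"))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinates") from exc
        if not (1 <= start <= genome_length and 1 <= end <= genome_length):
            raise ValueError(f"line {lineno}: coordinates {start}..{end} outside 1..{genome_length}")
        category = infer_category(name)
        features.append(
            GeneFeature(
                name=name,
                category=category,
                strand=strand,
                start=start,
                end=end,
                start_codon=col("start") or None,
                stop_codon=(col("stop") or None) if category == PCG else None,
                wraps_origin=start > end,
            )
        )
    return AnnotationTable(genome_length=genome_length, features=features)


def _parse_gff3(text: str, genome_length: int) -> AnnotationTable:
    features: list[GeneFeature] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"line {lineno}: GFF3 rows need 9 columns, got {len(cols)}")
        _, _, _, start_s, end_s, _, strand, _, attr_s = cols
        attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
        name = attrs.get("Name") or attrs.get("ID")
        if not name:
            raise ValueError(f"line {lineno}: feature without ID/Name")
        start, end = int(start_s), int(end_s)
        category = attrs.get("category") or infer_category(name)
        features.append(
            GeneFeature(
                name=name,
                category=category,
                strand=_STRAND_ALIASES.get(strand, "+"),
                start=start,
                end=end,
                start_codon=attrs.get("start_codon"),
                stop_codon=attrs.get("stop_codon"),
                wraps_origin=start > end,
            )
        )
    if not features:
        raise ValueError("empty annotation file")
    return AnnotationTable(genome_length=genome_length, features=features)


def parse_annotation(path: str | Path, genome_length: int) -> AnnotationTable:
    """Read an annotation from a Gene/Strand/From/To TSV or a GFF3 file.

    Categories are inferred from name prefixes (``tRNA-*`` -> tRNA, ``rrn*`` ->
    rRNA, ``CR*`` -> control region, anything else -> PCG) unless the GFF3
    carries an explicit ``category`` attribute.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith("##gff-version"):
        return _parse_gff3(text, genome_length)
    return _parse_table_tsv(text, genome_length)


def parse_annotation_text(text: str, genome_length: int) -> AnnotationTable:
    if text.lstrip().startswith("##gff-version"):
        return _parse_gff3(text, genome_length)
    return _parse_table_tsv(text, genome_length)


def read_fasta(path: str | Path, circular: bool = True) -> MitoGenome:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return MitoGenome(NucleotideSequence(record.id, str(record.seq)), circular=circular)


def write_fasta(genome: MitoGenome, path: str | Path, width: int = 70) -> None:
    bases = genome.seq.bases
    with open(path, "w") as fh:
        fh.write(f">{genome.seq.id}\n")
        for i in range(0, len(bases), width):
            fh.write(bases[i : i + width] + "\n")


def extract_feature_sequence(genome: MitoGenome, f: GeneFeature) -> NucleotideSequence:
    """Reading-strand sequence of a feature (reverse complement for '-')."""
    if f.start > genome.length or f.end > genome.length:
        raise ValueError(f"{f.name}: coordinates exceed genome length {genome.length}")
    if f.wraps_origin:
        plus = genome.slice(f.start, f.end)
    else:
        plus = genome.slice(f.start, f.end)
    bases = plus if f.strand == "+" else reverse_complement(plus)
    return NucleotideSequence(f.name, bases)


def position_in_feature(pos: int, f: GeneFeature, L: int | None = None) -> int:
    """1-based reading-strand offset of genome position ``pos`` inside ``f``."""
    if f.wraps_origin:
        if L is None:
            raise ValueError("genome length required for a wrapping feature")
        if not f.contains(pos, L):
            raise ValueError(f"position {pos} outside feature {f.name}")
        unrolled = pos if pos >= f.start else pos + L
        end_unrolled = f.end + L
        return unrolled - f.start + 1 if f.strand == "+" else end_unrolled - unrolled + 1
    if not f.start <= pos <= f.end:
        raise ValueError(f"position {pos} outside feature {f.name} ({f.start}..{f.end})")
    return pos - f.start + 1 if f.strand == "+" else f.end - pos + 1


def locate_position(pos: int, table: AnnotationTable) -> list[GeneFeature]:
    """All features whose interval contains ``pos`` (may be empty: intergenic).

    Overlapping genes yield more than one hit; a position inside a declared
    control region reports that control-region feature.
    """
    if not 1 <= pos <= table.genome_length:
        raise ValueError(f"position {pos} outside 1..{table.genome_length}")
    return [f for f in table.features if f.contains(pos, table.genome_length)]


@dataclass(frozen=True)
class SpacerRegion:
    """A maximal unannotated interval between two consecutive features."""

    start: int
    end: int
    length: int
    flanking: tuple[str, str]


def _sorted_noncr(table: AnnotationTable, include_control_regions: bool) -> list[GeneFeature]:
    feats = table.features if include_control_regions else [
        f for f in table.features if f.category != CONTROL_REGION
    ]
    return sorted(feats, key=lambda f: (f.start, f.end))


def intergenic_spacers(
    table: AnnotationTable,
    min_len: int = 10,
    convention: str = "bases",
    include_control_regions: bool = False,
) -> list[SpacerRegion]:
    """Maximal unannotated intervals between consecutive features on the circle.

    ``convention='bases'`` (default) measures the count of unannotated bases,
    next.start - prev.end - 1; ``'coord-diff'`` measures next.start - prev.end.
    Control regions are by default treated as unannotated (so they surface as
    spacers); pass ``include_control_regions=True`` to let them block spacers.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if convention not in {"bases", "coord-diff"}:
        raise ValueError(f"unknown gap convention {convention!r}")
    feats = _sorted_noncr(table, include_control_regions)
    if not feats:
        return []
    L = table.genome_length
    # Walk consecutive pairs by furthest end reached so far (features may nest).
    spacers: list[SpacerRegion] = []
    max_end = 0
    prev_name = ""
    for f in feats:
        if max_end and f.start > max_end + 1:
            gap_bases = f.start - max_end - 1
            length = gap_bases if convention == "bases" else f.start - max_end
            if length >= min_len:
                spacers.append(
                    SpacerRegion(max_end + 1, f.start - 1, length, (prev_name, f.name))
                )
        if f.end > max_end:
            max_end = f.end
            prev_name = f.name
    # circular wrap: gap between the last end and the first start
    first = feats[0]
    wrap_bases = (first.start - 1) + (L - max_end)
    if wrap_bases > 0:
        length = wrap_bases if convention == "bases" else wrap_bases + 1
        if length >= min_len:
            start = max_end + 1 if max_end < L else 1
            end = first.start - 1 if first.start > 1 else L
            spacers.append(SpacerRegion(start, end, length, (prev_name, first.name)))
    return spacers


def overlaps(table: AnnotationTable) -> list[tuple[str, str, int]]:
    """All feature pairs with intersecting intervals and the shared bp count.

    Intersection size is inclusive: features a..b and b..c share 1 bp.
    """
    feats = sorted(table.features, key=lambda f: (f.start, f.end))
    out: list[tuple[str, str, int]] = []
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            if b.start > a.end:
                break
            shared = min(a.end, b.end) - b.start + 1
            if shared > 0:
                out.append((a.name, b.name, shared))
    return out
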