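"""tRNA-punctuation transcription units and contig placement.

Mitochondrial polycistronic primary transcripts mature by excision of the
tRNAs that flank the genes; PCG/rRNA genes that are contiguous on a strand
with no intervening same-strand tRNA therefore end up on the same mature
(mono- or dicistronic) mRNA.  Control regions additionally break units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_model import (
    AnnotationTable,
    GeneFeature,
    MitoGenome,
    PCG,
    RRNA,
    TRNA,
    CONTROL_REGION,
)
from .mapper import GenomeIndex

__all__ = ["TranscriptionUnit", "predict_units", "ContigPlacement", "place_contigs"]


@dataclass(frozen=True)
class TranscriptionUnit:
    """A mature transcription unit: ordered PCG/rRNA members on one strand."""

    strand: str
    members: tuple[str, ...]

    @property
    def cistron_count(self) -> int:
        return len(self.members)

    @property
    def unit_id(self) -> str:
        return "-".join(self.members)


def predict_units(table: AnnotationTable, max_gap: int = 50) -> list[TranscriptionUnit]:
    """Partition PCG/rRNA genes into tRNA-punctuated transcription units.

    Separators are same-strand tRNAs and control regions (either strand).
    Consecutive genes additionally stay in one unit only when separated by at
    most ``max_gap`` bp of non-separator sequence (the known dicistronic pairs
    in insect mitogenomes actually overlap).
    """
    units: list[TranscriptionUnit] = []
    for strand in "+-":
        genes = [f for f in table.by_category(PCG, RRNA) if f.strand == strand]
        separators = [
            f
            for f in table.features
            if f.category == CONTROL_REGION or (f.category == TRNA and f.strand == strand)
        ]
        # order along transcription direction
        genes.sort(key=lambda f: f.start, reverse=(strand == "-"))
        current: list[GeneFeature] = []
        for g in genes:
            if not current:
                current = [g]
                continue
            prev = current[-1]
            if strand == "+":
                lo, hi = prev.end, g.start  # open interval between the two
                gap = g.start - prev.end - 1
            else:
                lo, hi = g.end, prev.start
                gap = prev.start - g.end - 1
            blocked = any(s.end > lo and s.start < hi for s in separators)
            if blocked or gap > max_gap:
                units.append(TranscriptionUnit(strand, tuple(f.name for f in current)))
                current = [g]
            else:
                current.append(g)
        if current:
            units.append(TranscriptionUnit(strand, tuple(f.name for f in current)))
    return units


@dataclass(frozen=True)
class ContigPlacement:
    """Best genome placement of an assembled transcript contig."""

    contig_id: str
    start: int | None
    end: int | None
    strand: str | None
    identity: float
    length: int
    genes_contained: tuple[str, ...] = ()
    genes_partial: tuple[str, ...] = ()

    @property
    def placed(self) -> bool:
        return self.start is not None


def _best_diagonal(index: GenomeIndex, seq: str, strand: str) -> tuple[int, int] | None:
    from collections import Counter
    from .genome_model import reverse_complement

    query = seq if strand == "+" else reverse_complement(seq)
    votes: Counter = Counter()
    k = index.k
    for off in range(0, len(query) - k + 1, k):
        for hit in index.index.get(query[off : off + k], ()):
            votes[(hit - off) % index.L] += 1
    if not votes:
        return None
    start0, n = votes.most_common(1)[0]
    return start0, n


def place_contigs(
    contigs,
    genome: MitoGenome,
    table: AnnotationTable,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
) -> list[ContigPlacement]:
    """Place contigs by seed-voted diagonal and full-length verification.

    ``contigs`` is an iterable of ``(id, sequence)`` pairs or a FASTA path.
    A placement is accepted when at least ``min_coverage`` of the contig
    aligns at >= ``min_identity``; genes (PCG/rRNA) fully inside the placed
    interval are reported as contained, intersecting ones as partial.
    """
    if isinstance(contigs, (str, Path)):
        from Bio import SeqIO

        contigs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(contigs), "fasta")]
    index = GenomeIndex(genome)
    from .genome_model import reverse_complement

    out: list[ContigPlacement] = []
    genes = table.by_category(PCG, RRNA)
    for contig_id, seq in contigs:
        seq = seq.upper()
        best = None
        for strand in "+-":
            diag = _best_diagonal(index, seq, strand)
            if diag is None:
                continue
            start0, _ = diag
            query = seq if strand == "+" else reverse_complement(seq)
            ref = index.doubled[start0 : start0 + len(query)]
            matches = sum(a == b for a, b in zip(query, ref))
            identity = matches / len(seq)
            if best is None or identity > best[2]:
                best = (start0, strand, identity)
        if best is None or best[2] < min_identity * min_coverage:
            out.append(ContigPlacement(contig_id, None, None, None, best[2] if best else 0.0, len(seq)))
            continue
        start0, strand, identity = best
        start, end = start0 + 1, start0 + len(seq)  # may run past L on the circle
        L = index.L
        contained, partial = [], []
        for g in genes:
            gs, ge = g.start, g.end
            # unroll the gene onto the doubled axis for circular placements
            for shift in (0, L):
                s, e = gs + shift, ge + shift
                if s >= start and e <= end:
                    contained.append(g.name)
                    break
                if s <= end and e >= start:
                    partial.append(g.name)
                    break
        out.append(
            ContigPlacement(
                contig_id,
                (start - 1) % L + 1,
                (end - 1) % L + 1,
                strand,
                identity,
                len(seq),
                tuple(contained),
                tuple(partial),
            )
        )
    return out
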