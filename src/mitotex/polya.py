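"""Poly(A) tail detection, junction placement and poly(A) signal scanning.

Reads carrying a terminal adenosine run (or a leading thymidine run when the
read reports the antisense of a polyadenylated transcript) are trimmed to
their transcribed body, the body is placed on the genome, and the junction --
the last transcribed base -- is located relative to the stop codon of the
nearest upstream gene on the same strand.  Genes with genome-encoded partial
stops (T or TA) whose junction falls exactly at the final encoded base have
their stop completed to TAA by the tail.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .genome_model import (
    AnnotationTable,
    GeneFeature,
    MitoGenome,
    PCG,
    RRNA,
    reverse_complement,
)
from .mapper import GenomeIndex, _trailing_run, _leading_run

__all__ = [
    "TailRead",
    "PolyAEvent",
    "PolyASignal",
    "DEFAULT_SIGNAL_MOTIFS",
    "read_fastq",
    "detect_tail_reads",
    "assign_polya_events",
    "find_polya_signals",
]

DEFAULT_SIGNAL_MOTIFS = ("AATAAA", "ATTAAA", "TATAAA", "AATAA")


@dataclass(frozen=True)
class TailRead:
    """A read with a detected terminal poly(A)/(T) run and its trimmed body."""

    read_id: str
    body: str
    side: str  # "3A" (sense poly(A)) or "5T" (antisense report)
    tail_len: int
    tail_base: str


@dataclass(frozen=True)
class PolyAEvent:
    """One read's polyadenylation junction relative to its gene's stop codon."""

    read_id: str
    junction: int  # genome bp of the last transcribed base
    strand: str
    tail_len: int
    tail_base: str
    gene: str
    offset_from_stop: int  # 0 = junction at the final stop-codon base
    completed_stop: str | None


@dataclass(frozen=True)
class PolyASignal:
    """A poly(A) signal motif occurrence upstream of a junction."""

    motif: str
    position: int  # genome bp of the motif's first (reading-strand) base
    strand: str
    distance_upstream: int


def read_fastq(path: str | Path):
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def detect_tail_reads(reads, min_tail: int = 9) -> list[TailRead]:
    """Find reads with a terminal base run of length >= ``min_tail``.

    The default of 9 reads the filter 'more than eight continuous A or T' as a
    strict inequality.  The 3' A run and 5' T run are both checked; the longer
    qualifying run wins.  Reads that are tail only are discarded.
    """
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    out: list[TailRead] = []
    for read_id, seq in reads:
        seq = seq.upper()
        a_run = _trailing_run(seq, "A")
        t_run = _leading_run(seq, "T")
        side = None
        if a_run >= min_tail or t_run >= min_tail:
            side = "3A" if a_run >= t_run else "5T"
        if side is None:
            continue
        if side == "3A":
            body, tail_len, base = seq[: len(seq) - a_run], a_run, "A"
        else:
            body, tail_len, base = seq[t_run:], t_run, "T"
        if not body:
            continue
        out.append(TailRead(read_id=read_id, body=body, side=side, tail_len=tail_len, tail_base=base))
    return out


def _reading_coord(pos: int, strand: str, L: int) -> int:
    return pos if strand == "+" else L - pos + 1


def _genome_coord(r: int, strand: str, L: int) -> int:
    return r if strand == "+" else L - r + 1


def _reading_seq(genome: MitoGenome, r_start: int, r_end: int, strand: str) -> str:
    """Reading-strand bases from reading coordinate r_start to r_end inclusive."""
    L = genome.length
    out = []
    for r in range(r_start, r_end + 1):
        pos = _genome_coord((r - 1) % L + 1, strand, L)
        b = genome.base(pos)
        if strand == "-":
            b = b.translate(_COMP)
        out.append(b)
    return "".join(out)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _stop_reading_end(f: GeneFeature, L: int) -> int:
    """Reading coordinate of the final (stop-adjacent) base of a gene."""
    return _reading_coord(f.end if f.strand == "+" else f.start, f.strand, L)


def assign_polya_events(
    tail_reads: list[TailRead],
    genome: MitoGenome,
    table: AnnotationTable,
    max_mismatches: int = 1,
    max_offset: int = 60,
    tail_margin: int = 2,
    index: GenomeIndex | None = None,
) -> tuple[list[PolyAEvent], Counter]:
    """Place tail-read bodies and keep junctions at/downstream of stop codons.

    The junction is the genome coordinate of the body's reading-strand 3' end.
    An event is kept when a same-strand PCG/rRNA has its final stop-codon base
    at most ``max_offset`` bp upstream of the junction (0 = at the stop); the
    nearest such gene wins.  To exclude genome-templated A runs masquerading
    as tails, the observed tail must exceed the genomic A run immediately
    downstream of the junction by at least ``tail_margin``.  Dropped reads are
    tallied by reason in the returned counter.
    """
    L = genome.length
    idx = index or GenomeIndex(genome)
    dropped: Counter = Counter()
    # reading-strand gene ends per strand, ascending
    ends: dict[str, list[tuple[int, GeneFeature]]] = {"+": [], "-": []}
    for f in table.by_category(PCG, RRNA):
        ends[f.strand].append((_stop_reading_end(f, L), f))
    for lst in ends.values():
        lst.sort()
    events: list[PolyAEvent] = []
    for tr in tail_reads:
        oriented = tr.body if tr.side == "3A" else reverse_complement(tr.body)
        placed = idx.map_body(oriented, max_mismatches)
        if placed is None:
            dropped["unmapped"] += 1
            continue
        if placed == "ambiguous":
            dropped["ambiguous"] += 1
            continue
        start, strand, _ = placed
        junction = start + len(oriented) - 1 if strand == "+" else start
        jr = _reading_coord(junction, strand, L)
        # Genomic A run just downstream of the mapped body end: those adenosines
        # are templated (the tail trimming cannot tell them from the tail), so
        # the junction extends over them and they are deducted from the tail.
        run = 0
        while run < tr.tail_len and _reading_seq(genome, jr + 1 + run, jr + 1 + run, strand) == "A":
            run += 1
        tail_len = tr.tail_len - run
        if tail_len < tail_margin:
            dropped["templated"] += 1
            continue
        jr += run
        junction = _genome_coord((jr - 1) % L + 1, strand, L)
        candidates = [(jr - er, f) for er, f in ends[strand] if er <= jr]
        candidates = [(off, f) for off, f in candidates if off <= max_offset]
        if not candidates:
            dropped["no_gene"] += 1
            continue
        offset, gene = min(candidates, key=lambda t: t[0])
        completed = None
        if gene.category == PCG and gene.stop_codon in {"T", "TA"} and offset == 0:
            completed = "TAA"
        events.append(
            PolyAEvent(
                read_id=tr.read_id,
                junction=junction,
                strand=strand,
                tail_len=tail_len,
                tail_base=tr.tail_base,
                gene=gene.name,
                offset_from_stop=offset,
                completed_stop=completed,
            )
        )
    return events, dropped


def find_polya_signals(
    genome: MitoGenome,
    event: PolyAEvent,
    motifs: tuple[str, ...] = DEFAULT_SIGNAL_MOTIFS,
    window: tuple[int, int] = (8, 229),
) -> list[PolyASignal]:
    """All motif occurrences on the reading strand within the upstream window.

    ``distance_upstream`` is measured from the motif's last base to the
    junction (the first tail base sits one position downstream of it).
    """
    L = genome.length
    min_d, max_d = window
    jr = _reading_coord(event.junction, event.strand, L)
    lo = jr - max_d - max(len(m) for m in motifs) + 1
    region = _reading_seq(genome, lo, jr, event.strand)
    hits: list[PolyASignal] = []
    for motif in motifs:
        for m in re.finditer(f"(?={motif})", region):
            r_start = lo + m.start()
            r_end = r_start + len(motif) - 1
            dist = jr - r_end
            if min_d <= dist <= max_d:
                pos = _genome_coord((r_start - 1) % L + 1, event.strand, L)
                hits.append(
                    PolyASignal(motif=motif, position=pos, strand=event.strand, distance_upstream=dist)
                )
    hits.sort(key=lambda h: h.distance_upstream)
    return hits
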