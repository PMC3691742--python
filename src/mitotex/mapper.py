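"""Exact-match read mapper for a small circular genome.

A k-mer seeded, mismatch-bounded matcher sized for desk-scale mitochondrial
work (a ~16 kb circle): every genome k-mer of both strands is indexed, read
bodies are verified base-by-base at each seeded candidate, and reads with more
than one best-scoring placement are reported ambiguous rather than placed.
Terminal poly(A) (3') and poly(T) (5') runs are soft-clipped before mapping so
polyadenylated reads anchor on their transcribed body.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import MitoGenome, reverse_complement
from .expression import ReadAlignment

__all__ = ["GenomeIndex", "MapStats", "map_reads"]


def _trailing_run(seq: str, base: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def _leading_run(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


@dataclass
class MapStats:
    mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    too_short: int = 0


class GenomeIndex:
    """Seed index of a circular genome (k-mers of the doubled sequence)."""

    def __init__(self, genome: MitoGenome, k: int = 20):
        self.k = k
        self.L = genome.length
        self.doubled = genome.seq.bases + genome.seq.bases
        self.doubled_rc = reverse_complement(genome.seq.bases) * 2
        index: dict[str, list[int]] = {}
        for i in range(self.L):
            index.setdefault(self.doubled[i : i + k], []).append(i)
        self.index = index

    def _verify(self, body: str, start0: int, max_mm: int) -> int | None:
        ref = self.doubled[start0 : start0 + len(body)]
        mm = 0
        for a, b in zip(body, ref):
            if a != b:
                mm += 1
                if mm > max_mm:
                    return None
        return mm

    def map_body(self, body: str, max_mismatches: int = 2) -> tuple[int, str, int] | None | str:
        """Best placement of ``body``: (1-based start, strand, mismatches).

        Returns None when unplaceable, the string 'ambiguous' when more than
        one distinct best placement exists.
        """
        n = len(body)
        if n < self.k:
            return None
        best: dict[tuple[int, str], int] = {}
        for strand in "+-":
            query = body if strand == "+" else reverse_complement(body)
            offsets = {0, n - self.k, (n - self.k) // 2}
            for off in offsets:
                for hit in self.index.get(query[off : off + self.k], ()):
                    start0 = (hit - off) % self.L
                    key = (start0, strand)
                    if key in best:
                        continue
                    mm = self._verify(query, start0, max_mismatches)
                    if mm is not None:
                        best[key] = mm
        if not best:
            return None
        top = min(best.values())
        winners = [key for key, mm in best.items() if mm == top]
        if len(winners) > 1:
            return "ambiguous"
        (start0, strand) = winners[0]
        return start0 + 1, strand, top


def map_reads(
    reads,
    genome: MitoGenome,
    max_mismatches: int = 2,
    min_clip: int = 1,
    trim_tails: bool = True,
    k: int = 20,
) -> tuple[list[ReadAlignment], MapStats]:
    """Map an iterable of ``(read_id, sequence)`` pairs onto the genome.

    Any terminal 3' A run / 5' T run of at least ``min_clip`` is soft-clipped
    before placement: a read ending a few bases into a poly(A) tail cannot be
    told apart from one ending in a templated A run, and leaving those bases
    in would scatter spurious mismatches just downstream of poly(A)
    junctions.  The stored alignment sequence is plus-strand oriented so
    downstream pileup needs no further complementing; ``clip`` records the
    soft-clipped tail length.
    """
    index = GenomeIndex(genome, k=k)
    stats = MapStats()
    out: list[ReadAlignment] = []
    for read_id, seq in reads:
        seq = seq.upper()
        clip = 0
        body = seq
        if trim_tails:
            ta = _trailing_run(body, "A")
            if ta >= min_clip:
                body = body[: len(body) - ta]
                clip += ta
            tt = _leading_run(body, "T")
            if tt >= min_clip:
                body = body[tt:]
                clip += tt
        if len(body) < index.k:
            stats.too_short += 1
            continue
        placed = index.map_body(body, max_mismatches)
        if placed is None:
            stats.unmapped += 1
            continue
        if placed == "ambiguous":
            stats.ambiguous += 1
            continue
        start, strand, mm = placed
        plus_seq = body if strand == "+" else reverse_complement(body)
        out.append(
            ReadAlignment(
                read_id=read_id,
                start=start,
                strand=strand,
                length=len(body),
                clip=clip,
                seq=plus_seq,
                mismatches=mm,
            )
        )
        stats.mapped += 1
    return out, stats
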