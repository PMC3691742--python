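"""Tandem repeats, regulatory motifs and stem-loops in control regions.

Insect mitochondrial control regions (A+T-rich regions) carry tandem repeat
arrays, poly-T stretches, TATA boxes, G[A]nT motifs, TA(A)n-like stretches,
the mTERF consensus ACTAA, and inverted repeats able to form stem-loops
associated with replication/transcription origins.  Detection here is exact-
first with bounded mismatches; no thermodynamic folding is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome_model import NucleotideSequence, reverse_complement

__all__ = [
    "TandemRepeat",
    "find_tandem_repeats",
    "MotifHit",
    "MOTIF_PATTERNS",
    "scan_motifs",
    "StemLoop",
    "find_stem_loops",
]


@dataclass(frozen=True)
class TandemRepeat:
    """A tandem array: >= 2 copies of a unit, partial final copy allowed.

    ``start`` is 1-based within the scanned region; ``copy_number`` counts
    full copies plus the fractional final copy; ``mismatches`` lists the
    mismatch count of each full copy against the consensus (first copy).
    """

    start: int
    unit_length: int
    copy_number: float
    consensus: str
    mismatches: tuple[int, ...]

    @property
    def span(self) -> int:
        return round(self.copy_number * self.unit_length)

    @property
    def end(self) -> int:
        return self.start + self.span - 1


def _hamming(a: str, b: str, limit: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def find_tandem_repeats(
    region: str | NucleotideSequence,
    min_unit: int = 3,
    max_unit: int = 200,
    max_mismatch_frac: float = 0.1,
) -> list[TandemRepeat]:
    """Maximal non-overlapping tandem arrays by seeded self-match.

    For every candidate unit length the region is scanned for positions where
    the next block repeats the unit within the mismatch budget; arrays are
    extended greedily (full copies, then a partial final copy) and overlapping
    candidates are resolved longest-span-first, then smallest-unit-first.
    """
    s = (region.bases if isinstance(region, NucleotideSequence) else region).upper()
    n = len(s)
    candidates: list[TandemRepeat] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        limit = int(u * max_mismatch_frac)
        i = 0
        while i + 2 * u <= n:
            unit = s[i : i + u]
            # cheap exact prefilter before the mismatch-tolerant comparison
            probe = min(u, 8)
            if s[i : i + probe] != s[i + u : i + u + probe]:
                i += 1
                continue
            mms: list[int] = [0]
            j = i + u
            while j + u <= n:
                mm = _hamming(unit, s[j : j + u], limit)
                if mm is None:
                    break
                mms.append(mm)
                j += u
            if len(mms) < 2:
                i += 1
                continue
            # partial final copy: longest exact unit prefix
            partial = 0
            while j + partial < n and partial < u and s[j + partial] == unit[partial]:
                partial += 1
            candidates.append(
                TandemRepeat(
                    start=i + 1,
                    unit_length=u,
                    copy_number=len(mms) + partial / u,
                    consensus=unit,
                    mismatches=tuple(mms),
                )
            )
            i = j  # restart after the array to keep arrays maximal
        # fallthrough: next unit length
    candidates.sort(key=lambda r: (-r.span, r.unit_length, r.start))
    chosen: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


MOTIF_PATTERNS: dict[str, str] = {
    "polyT": r"T{5,}",
    "TATA": r"TATA",
    "GA_nT": r"GA{2,}T",
    "TAA_n_like": r"(?:TAA){3,}",
    "ATAA_n_like": r"A(?:TAA?){3,}",
    "mTERF_ACTAA": r"ACTAA",
}


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int  # 1-based within the scanned region, on the given strand
    strand: str
    matched: str


def scan_motifs(
    region: str | NucleotideSequence,
    motifs: tuple[str, ...] | None = None,
    both_strands: bool = False,
) -> list[MotifHit]:
    """All occurrences of the named motif patterns in a region.

    Matches are maximal (greedy) and non-overlapping per motif.  With
    ``both_strands`` the reverse complement is scanned too; minus-strand
    positions refer to the reverse-complemented sequence.
    """
    s = (region.bases if isinstance(region, NucleotideSequence) else region).upper()
    names = motifs or tuple(MOTIF_PATTERNS)
    hits: list[MotifHit] = []
    strands = [("+", s)] + ([("-", reverse_complement(s))] if both_strands else [])
    for name in names:
        pattern = MOTIF_PATTERNS.get(name)
        if pattern is None:
            raise ValueError(f"unknown motif {name!r}; known: {sorted(MOTIF_PATTERNS)}")
        for strand, seq in strands:
            for m in re.finditer(pattern, seq):
                hits.append(MotifHit(name, m.start() + 1, strand, m.group()))
    hits.sort(key=lambda h: (h.strand, h.position))
    return hits


@dataclass(frozen=True)
class StemLoop:
    """An exact inverted repeat: 5' arm, loop, 3' arm (1-based inclusive)."""

    arm5: tuple[int, int]
    loop: tuple[int, int]
    arm3: tuple[int, int]

    @property
    def stem_length(self) -> int:
        return self.arm5[1] - self.arm5[0] + 1

    @property
    def loop_length(self) -> int:
        return self.loop[1] - self.loop[0] + 1

    @property
    def span(self) -> tuple[int, int]:
        return self.arm5[0], self.arm3[1]


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def find_stem_loops(
    region: str | NucleotideSequence,
    min_stem: int = 3,
    loop_range: tuple[int, int] = (3, 20),
) -> list[StemLoop]:
    """All maximal exact inverted repeats with loop length inside the bounds.

    Stems are extended as far as bases pair exactly; hits nested inside a
    larger hit's span are suppressed.
    """
    s = (region.bases if isinstance(region, NucleotideSequence) else region).upper()
    n = len(s)
    lo, hi = loop_range
    raw: list[StemLoop] = []
    for a in range(n):  # a = 0-based loop start
        for l in range(lo, hi + 1):
            b = a + l - 1  # loop end
            if b + 1 >= n or a == 0:
                continue
            k = 0
            while a - 1 - k >= 0 and b + 1 + k < n and _PAIR.get(s[a - 1 - k]) == s[b + 1 + k]:
                k += 1
            if k >= min_stem:
                raw.append(
                    StemLoop(
                        arm5=(a - k + 1, a),
                        loop=(a + 1, b + 1),
                        arm3=(b + 2, b + 1 + k),
                    )
                )
    # suppress hits nested within a larger hit's total span
    raw.sort(key=lambda h: (-(h.span[1] - h.span[0]), h.span[0]))
    kept: list[StemLoop] = []
    for h in raw:
        if not any(h.span[0] >= k2.span[0] and h.span[1] <= k2.span[1] for k2 in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.span)
    return kept
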