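"""Per-base read depth and per-feature expression from read alignments.

Expression follows the reads-per-base convention: mapped reads overlapping a
feature are summed and divided by the feature length.  Relative qPCR
expression uses the 2^-ddCt transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_model import AnnotationTable, feature_length, intergenic_spacers

__all__ = [
    "ReadAlignment",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_sam",
    "compute_depth",
    "ExpressionRecord",
    "expression_levels",
    "fold_change",
    "write_bedgraph",
]


@dataclass(frozen=True)
class ReadAlignment:
    """An ungapped read placement on the circular genome.

    ``start`` is the 1-based plus-strand leftmost position; ``seq`` (optional)
    holds the aligned bases already oriented to the plus strand; ``clip`` is
    the soft-clipped poly(A)/poly(T) tail length removed before placement.
    """

    read_id: str
    start: int
    strand: str
    length: int
    clip: int = 0
    seq: str | None = None
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("aligned length must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


def write_alignments_tsv(alignments: list[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tstrand\tlength\tclip\tmismatches\tseq\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.start}\t{a.strand}\t{a.length}\t{a.clip}\t{a.mismatches}\t{a.seq or ''}\n"
            )


def read_alignments_tsv(path: str | Path) -> list[ReadAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            out.append(
                ReadAlignment(
                    read_id=cols[idx["read_id"]],
                    start=int(cols[idx["start"]]),
                    strand=cols[idx["strand"]],
                    length=int(cols[idx["length"]]),
                    clip=int(cols[idx.get("clip", 4)] or 0),
                    mismatches=int(cols[idx.get("mismatches", 5)] or 0),
                    seq=cols[idx["seq"]] or None if "seq" in idx and len(cols) > idx["seq"] else None,
                )
            )
    return out


def read_sam(path: str | Path) -> list[ReadAlignment]:
    """Load primary mapped records of a SAM/BAM file as ReadAlignments."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            clip = sum(n for op, n in (rec.cigartuples or ()) if op == 4)
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    start=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    length=rec.reference_length or len(rec.query_sequence or ""),
                    clip=clip,
                    seq=rec.query_alignment_sequence,
                )
            )
    return out


def compute_depth(alignments: list[ReadAlignment], L: int) -> np.ndarray:
    """Per-position read counts over [1..L] (index 0 = position 1), circular."""
    depth = np.zeros(L, dtype=np.int64)
    for a in alignments:
        if a.length > 2 * L:
            raise ValueError(f"alignment {a.read_id} longer than twice the genome")
        idx = (np.arange(a.start - 1, a.start - 1 + a.length)) % L
        np.add.at(depth, idx, 1)
    return depth


def _intervals(start: int, length: int, L: int) -> list[tuple[int, int]]:
    """1-based inclusive linear intervals of a possibly wrapping span."""
    end = start + length - 1
    if end <= L:
        return [(start, end)]
    return [(start, L), (1, end - L)]


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


@dataclass(frozen=True)
class ExpressionRecord:
    """Reads-per-base expression of one feature (or spacer)."""

    name: str
    category: str
    mapped_reads: int
    length: int
    level: float


def expression_levels(
    alignments: list[ReadAlignment],
    table: AnnotationTable,
    min_overlap: int = 1,
    count_mode: str = "any-overlap",
    include_spacers: bool = True,
    min_spacer: int = 10,
) -> list[ExpressionRecord]:
    """Reads-per-base expression for every feature (plus spacers), sorted
    descending by level.

    ``count_mode='any-overlap'`` counts a read toward every feature it overlaps
    by at least ``min_overlap`` bp (reads over overlapping genes or dicistronic
    junctions count twice); ``'majority'`` assigns each read only to the
    feature with the largest overlap.
    """
    if count_mode not in {"any-overlap", "majority"}:
        raise ValueError(f"unknown count mode {count_mode!r}")
    L = table.genome_length
    targets: list[tuple[str, str, list[tuple[int, int]], int]] = []
    for f in table.features:
        flen = feature_length(f, L)
        if flen < 1:
            raise ValueError(f"zero-length feature {f.name}")
        ivs = _intervals(f.start, flen, L) if f.wraps_origin else [(f.start, f.end)]
        targets.append((f.name, f.category, ivs, flen))
    if include_spacers:
        for sp in intergenic_spacers(table, min_len=min_spacer, include_control_regions=True):
            targets.append(
                (f"spacer:{sp.flanking[0]}-{sp.flanking[1]}", "spacer", [(sp.start, sp.end)], sp.length)
            )
    counts = {name: 0 for name, _, _, _ in targets}
    for a in alignments:
        read_ivs = _intervals(a.start, a.length, L)
        if count_mode == "any-overlap":
            for name, _, ivs, _ in targets:
                if _overlap_bp(read_ivs, ivs) >= min_overlap:
                    counts[name] += 1
        else:
            best_name, best_ov = None, 0
            for name, _, ivs, _ in targets:
                ov = _overlap_bp(read_ivs, ivs)
                if ov > best_ov:
                    best_name, best_ov = name, ov
            if best_name is not None and best_ov >= min_overlap:
                counts[best_name] += 1
    records = [
        ExpressionRecord(name=name, category=cat, mapped_reads=counts[name], length=flen, level=counts[name] / flen)
        for name, cat, _, flen in targets
    ]
    records.sort(key=lambda r: (-r.level, r.name))
    return records


def fold_change(delta_delta_ct: float) -> float:
    """Relative expression by the 2^-ddCt method."""
    return 2.0 ** (-delta_delta_ct)


def write_bedgraph(depth: np.ndarray, path: str | Path, chrom: str = "mitogenome") -> None:
    """Write a run-length-compressed bedGraph (0-based half-open) of depth."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={chrom}_depth\n")
        start = 0
        current = int(depth[0]) if len(depth) else 0
        for i in range(1, len(depth) + 1):
            val = int(depth[i]) if i < len(depth) else None
            if val != current:
                fh.write(f"{chrom}\t{start}\t{i}\t{current}\n")
                start, current = i, val
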