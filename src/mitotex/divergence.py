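"""Pairwise comparative statistics between orthologous mitochondrial PCGs.

Covers codon-aware ortholog alignment (protein-guided), divergence partitioned
by site degeneracy (nondegenerate / fourfold) and CpG context, transition/
transversion ratios, Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction,
and AT/GC strand skews.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from .genome_model import NucleotideSequence
from .mito_code import (
    GeneticCode,
    INVERTEBRATE_MITO,
    classify_site,
    NONDEGENERATE,
    FOURFOLD,
    STOP,
)

__all__ = [
    "AlignedPair",
    "align_orthologs",
    "DivergenceCell",
    "DivergenceReport",
    "partition_divergence",
    "KaKsResult",
    "ka_ks",
    "SkewResult",
    "skew",
]

_BASES = set("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class AlignedPair:
    """A codon-aware gapped alignment of two orthologous CDS (frame at col 1)."""

    gene: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("aligned length must be a codon multiple")


def _trim_to_codons(bases: str) -> str:
    return bases[: len(bases) - len(bases) % 3]


def align_orthologs(
    cds_a: str | NucleotideSequence,
    cds_b: str | NucleotideSequence,
    code: GeneticCode = INVERTEBRATE_MITO,
    gene: str = "",
) -> AlignedPair:
    """Protein-guided global alignment back-translated to nucleotides.

    Sequences are trimmed to complete codons (dropping any partial stop),
    translated, globally aligned at the protein level (identity scoring with
    affine gaps) and the alignment is projected back onto codons, so gaps come
    in multiples of three.
    """
    from Bio.Align import PairwiseAligner

    a = _trim_to_codons(cds_a.bases if isinstance(cds_a, NucleotideSequence) else cds_a.upper())
    b = _trim_to_codons(cds_b.bases if isinstance(cds_b, NucleotideSequence) else cds_b.upper())
    if not a or not b:
        raise ValueError("empty coding sequence")
    prot_a = "".join(code.aa(a[i : i + 3]) for i in range(0, len(a), 3))
    prot_b = "".join(code.aa(b[i : i + 3]) for i in range(0, len(b), 3))
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a.replace(STOP, "x"), prot_b.replace(STOP, "x"))[0]
    pa, pb = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(pa, pb):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(a[ia : ia + 3])
            ia += 3
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(b[ib : ib + 3])
            ib += 3
    return AlignedPair(gene=gene, seq_a="".join(out_a), seq_b="".join(out_b))


# ---------------------------------------------------------------------------
# partitioned divergence


@dataclass
class DivergenceCell:
    """Divergence statistics for one (site class, CpG context) cell."""

    n_sites: int = 0
    n_diff: int = 0
    transitions: int = 0
    transversions: int = 0

    @property
    def pct(self) -> float | None:
        if self.n_sites == 0:
            return None
        return 100.0 * self.n_diff / self.n_sites

    @property
    def se(self) -> float | None:
        """Analytic binomial standard error of the difference proportion."""
        if self.n_sites == 0:
            return None
        p = self.n_diff / self.n_sites
        return math.sqrt(p * (1 - p) / self.n_sites)

    @property
    def compared_kb(self) -> float:
        return self.n_sites / 1000.0

    @property
    def ts_tv(self) -> float | None:
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


@dataclass
class DivergenceReport:
    """Table of divergence cells over {all, nd, 4d} x {all, nonCpG, CpG}."""

    cells: dict[tuple[str, str], DivergenceCell] = field(default_factory=dict)
    pct_cpg: dict[str, float | None] = field(default_factory=dict)
    pct_gc: dict[str, float | None] = field(default_factory=dict)

    def cell(self, site_class: str, context: str) -> DivergenceCell:
        return self.cells[(site_class, context)]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for (cls, ctx), c in self.cells.items():
            rows.append(
                {
                    "class": cls,
                    "context": ctx,
                    "pct_difference": c.pct,
                    "se": c.se,
                    "compared_kb": c.compared_kb,
                    "ts_tv": c.ts_tv,
                    "pct_cpg_of_class": self.pct_cpg.get(cls),
                    "pct_gc_of_class": self.pct_gc.get(cls),
                }
            )
        return pd.DataFrame(rows)


def _cpg_flags(seq: str) -> list[bool]:
    """Per-position CpG-context flags on an ungapped-with-gaps string.

    A position is CpG-context if its base is the C of a CG dinucleotide or the
    G preceded by C, looking through alignment gaps.
    """
    n = len(seq)
    flags = [False] * n
    prev_idx = None
    for i, b in enumerate(seq):
        if b == "-":
            continue
        if prev_idx is not None:
            if seq[prev_idx] == "C" and b == "G":
                flags[prev_idx] = True
                flags[i] = True
        prev_idx = i
    return flags


def partition_divergence(
    pairs: AlignedPair | list[AlignedPair],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> DivergenceReport:
    """Divergence partitioned by degeneracy class and CpG context.

    Site degeneracy and CpG context are classified on the first (reference)
    sequence of each pair.  Compared sites in a cell are ungapped columns
    falling in that class-context intersection; cells with zero compared sites
    report ``None`` rather than zero.
    """
    if isinstance(pairs, AlignedPair):
        pairs = [pairs]
    classes = ("all", "nd", "4d")
    contexts = ("all", "nonCpG", "CpG")
    report = DivergenceReport(
        cells={(cls, ctx): DivergenceCell() for cls in classes for ctx in contexts}
    )
    comp = {cls: {"cpg": 0, "gc": 0, "n": 0} for cls in classes}
    for pair in pairs:
        a, b = pair.seq_a, pair.seq_b
        cpg = _cpg_flags(a)
        for col in range(len(a)):
            ba, bb = a[col], b[col]
            if ba not in _BASES or bb not in _BASES:
                continue
            codon_start = col - col % 3
            codon_a = a[codon_start : codon_start + 3]
            site_classes = ["all"]
            if set(codon_a) <= _BASES:
                deg = classify_site(codon_a, col % 3 + 1, code)
                if deg == NONDEGENERATE:
                    site_classes.append("nd")
                elif deg == FOURFOLD:
                    site_classes.append("4d")
            ctx = "CpG" if cpg[col] else "nonCpG"
            diff = ba != bb
            is_ts = frozenset((ba, bb)) in _TRANSITIONS
            for cls in site_classes:
                comp[cls]["n"] += 1
                comp[cls]["cpg"] += cpg[col]
                comp[cls]["gc"] += ba in "GC"
                for c in ("all", ctx):
                    cell = report.cells[(cls, c)]
                    cell.n_sites += 1
                    if diff:
                        cell.n_diff += 1
                        if is_ts:
                            cell.transitions += 1
                        else:
                            cell.transversions += 1
    for cls in classes:
        n = comp[cls]["n"]
        report.pct_cpg[cls] = 100.0 * comp[cls]["cpg"] / n if n else None
        report.pct_gc[cls] = 100.0 * comp[cls]["gc"] / n if n else None
    return report


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks


@dataclass(frozen=True)
class KaKsResult:
    """Nonsynonymous (Ka) and synonymous (Ks) rates and their ratio."""

    gene: str
    ka: float | None
    ks: float | None
    ratio: float | None
    n_sites: float = 0.0
    s_sites: float = 0.0
    n_diff: float = 0.0
    s_diff: float = 0.0


def _syn_fraction(codon: str, code: GeneticCode) -> float:
    """Number of synonymous sites in a codon (0..3) under equal-rate counting."""
    total = 0.0
    aa0 = code.aa(codon)
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code.aa(alt) == aa0 and aa0 != STOP:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_counts(ca: str, cb: str, code: GeneticCode) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all pathways.

    A mutational step is synonymous iff it preserves a non-stop amino acid;
    steps to, from or between stop codons count as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    paths = list(permutations(diff_pos))
    for path in paths:
        cur = ca
        for pos in path:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = code.aa(cur), code.aa(nxt)
            if aa_cur == aa_nxt and aa_cur != STOP:
                syn_total += 1
            else:
                nonsyn_total += 1
            cur = nxt
    n = len(paths)
    return syn_total / n, nonsyn_total / n


def _jukes_cantor(p: float) -> float | None:
    # tolerance keeps proportions landing exactly on the 3/4 saturation
    # boundary (possible on very short pairs) deterministically undefined
    if p >= 0.75 - 1e-9:
        return None
    return -0.75 * math.log(1 - 4.0 * p / 3.0) + 0.0  # avoid -0.0


def ka_ks(pair: AlignedPair, code: GeneticCode = INVERTEBRATE_MITO) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor multiple-hit correction.

    Codon columns containing gaps, ambiguous bases or a stop codon in either
    sequence are excluded.  The ratio is ``None`` (undefined) when Ks is zero
    or a proportion exceeds the Jukes-Cantor domain.
    """
    S = N = 0.0
    Sd = Nd = 0.0
    for i in range(0, len(pair.seq_a), 3):
        ca, cb = pair.seq_a[i : i + 3], pair.seq_b[i : i + 3]
        if set(ca) - _BASES or set(cb) - _BASES:
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        sa, sb = _syn_fraction(ca, code), _syn_fraction(cb, code)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        ds, dn = _pathway_counts(ca, cb, code)
        Sd += ds
        Nd += dn
    ks = _jukes_cantor(Sd / S) if S > 0 else None
    ka = _jukes_cantor(Nd / N) if N > 0 else None
    if ka is None or ks is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(gene=pair.gene, ka=ka, ks=ks, ratio=ratio, n_sites=N, s_sites=S, n_diff=Nd, s_diff=Sd)


# ---------------------------------------------------------------------------
# strand skews


@dataclass(frozen=True)
class SkewResult:
    """AT skew (A-T)/(A+T) and GC skew (G-C)/(G+C); None when undefined."""

    at_skew: float | None
    gc_skew: float | None


def skew(seq: str | NucleotideSequence) -> SkewResult:
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq.upper()
    if not bases:
        raise ValueError("empty sequence")
    a, t = bases.count("A"), bases.count("T")
    g, c = bases.count("G"), bases.count("C")
    at = (a - t) / (a + t) if a + t else None
    gc = (g - c) / (g + c) if g + c else None
    return SkewResult(at_skew=at, gc_skew=gc)
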