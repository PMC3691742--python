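"""Invertebrate mitochondrial genetic code: translation, degeneracy, codon usage.

The default code is NCBI translation table 5 (invertebrate mitochondrial),
under which ATA encodes Met, AGA/AGG encode Ser, and TGA encodes Trp.  Any
NCBI table id can be selected.  Stop codons are rendered as ``*``.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import product

from .genome_model import NucleotideSequence, AnnotationTable, MitoGenome, extract_feature_sequence

__all__ = [
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "translate",
    "classify_site",
    "NONDEGENERATE",
    "TWOFOLD",
    "FOURFOLD",
    "OTHER",
    "CodonUsageTable",
    "codon_usage",
    "complete_stop_codon",
    "StartStopProfile",
    "tabulate_start_stop",
]

STOP = "*"
_BASES = "ACGT"

NONDEGENERATE = "nondegenerate"
TWOFOLD = "twofold"
FOURFOLD = "fourfold"
OTHER = "other"


class GeneticCode:
    """A 64-entry codon table (NCBI numbering; 5 = invertebrate mitochondrial)."""

    def __init__(self, table_id: int = 5):
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = {}
        for codon in ("".join(p) for p in product(_BASES, repeat=3)):
            if codon in table.stop_codons:
                self.codon_to_aa[codon] = STOP
            else:
                self.codon_to_aa[codon] = table.forward_table[codon]
        assert len(self.codon_to_aa) == 64

    def aa(self, codon: str) -> str:
        """Amino-acid letter for a codon; ``*`` for stop, ``X`` for ambiguity."""
        return self.codon_to_aa.get(codon.upper(), "X")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon.upper()) == STOP

    def synonymous_family(self, codon: str) -> list[str]:
        target = self.aa(codon)
        return [c for c, a in self.codon_to_aa.items() if a == target]


INVERTEBRATE_MITO = GeneticCode(5)


def translate(cds: str | NucleotideSequence, code: GeneticCode = INVERTEBRATE_MITO, to_stop: bool = False) -> str:
    """Codon-by-codon translation; stops rendered as ``*``.

    A trailing partial codon (1-2 nt) is ignored.  Codons containing non-ACGT
    bases translate to ``X`` with a warning.  With ``to_stop`` the protein is
    truncated at the first stop codon.
    """
    bases = cds.bases if isinstance(cds, NucleotideSequence) else cds.upper()
    if len(bases) < 3:
        raise ValueError("coding sequence shorter than one codon")
    out = []
    for i in range(0, len(bases) - len(bases) % 3, 3):
        codon = bases[i : i + 3]
        aa = code.aa(codon)
        if aa == "X":
            warnings.warn(f"ambiguous codon {codon!r} at position {i + 1} translated as X")
        if aa == STOP and to_stop:
            break
        out.append(aa)
    return "".join(out)


def classify_site(codon: str, position: int, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Degeneracy class of one codon position (1..3).

    Fourfold: all three substitutions preserve the amino acid.  Nondegenerate:
    all three change it (a change to or from STOP counts as a change).
    One preserving substitution -> twofold; two -> other (threefold).
    Codons with ambiguous bases, and stop codons themselves, classify as other.
    """
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    if set(codon) - set(_BASES) or len(codon) != 3:
        return OTHER
    ref_aa = code.aa(codon)
    if ref_aa == STOP:
        return OTHER
    preserved = 0
    i = position - 1
    for b in _BASES:
        if b == codon[i]:
            continue
        alt = codon[:i] + b + codon[i + 1 :]
        if code.aa(alt) == ref_aa:
            preserved += 1
    return {0: NONDEGENERATE, 1: TWOFOLD, 2: OTHER, 3: FOURFOLD}[preserved]


@dataclass
class CodonUsageTable:
    """Codon counts and relative synonymous codon usage (RSCU)."""

    counts: dict[str, int] = field(default_factory=dict)
    rscu: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self, code: GeneticCode = INVERTEBRATE_MITO):
        import pandas as pd

        rows = [
            {"codon": c, "aa": code.aa(c), "count": self.counts.get(c, 0), "rscu": self.rscu.get(c, float("nan"))}
            for c in sorted(code.codon_to_aa)
        ]
        return pd.DataFrame(rows)


def codon_usage(
    cds_set: list[str | NucleotideSequence],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonUsageTable:
    """Codon counts and RSCU over a set of coding sequences.

    Stop codons are included in the counts (they form their own synonymous
    family).  Trailing partial codons and codons containing N are skipped.
    RSCU(c) = count(c) * family_size / family_total when the family is observed.
    """
    counts: Counter[str] = Counter()
    for cds in cds_set:
        bases = cds.bases if isinstance(cds, NucleotideSequence) else cds.upper()
        for i in range(0, len(bases) - len(bases) % 3, 3):
            codon = bases[i : i + 3]
            if set(codon) <= set(_BASES):
                counts[codon] += 1
    families: dict[str, list[str]] = defaultdict(list)
    for codon, aa in code.codon_to_aa.items():
        families[aa].append(codon)
    rscu: dict[str, float] = {}
    for aa, codons in families.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        size = len(codons)
        for c in codons:
            rscu[c] = counts.get(c, 0) * size / total
    return CodonUsageTable(counts=dict(counts), rscu=rscu)


def complete_stop_codon(partial: str) -> tuple[str, int]:
    """Complete a (possibly partial) stop codon by polyadenylation.

    Genome-encoded T or TA termini are completed to TAA by the poly(A) tail;
    returns the completed codon and the number of adenosines contributed.
    """
    partial = partial.upper()
    if partial in {"TAA", "TAG"}:
        return partial, 0
    if partial == "TA":
        return "TAA", 1
    if partial == "T":
        return "TAA", 2
    raise ValueError(f"not a (partial) stop codon: {partial!r}")


@dataclass
class StartStopProfile:
    """Per-species start/stop codon assignments and frequencies for PCGs."""

    per_gene: dict[str, dict[str, tuple[str | None, str | None]]] = field(default_factory=dict)
    start_freq: dict[str, Counter] = field(default_factory=dict)
    stop_freq: dict[str, Counter] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def partial_stop_genes(self, species: str) -> list[str]:
        return sorted(
            g for g, (_, stop) in self.per_gene.get(species, {}).items() if stop in {"T", "TA"}
        )


def tabulate_start_stop(
    species: list[tuple[str, AnnotationTable] | tuple[str, AnnotationTable, MitoGenome]],
) -> StartStopProfile:
    """Tabulate start/stop codon usage of PCGs across species.

    Codons are taken from the annotation's Start/Stop columns; when absent and
    a genome is supplied, they are read off the reading-strand gene sequence.
    Genes with no recoverable start codon are excluded with a note.
    """
    profile = StartStopProfile()
    for entry in species:
        name, table = entry[0], entry[1]
        genome = entry[2] if len(entry) > 2 else None
        profile.per_gene[name] = {}
        starts: Counter = Counter()
        stops: Counter = Counter()
        for f in table.pcgs:
            start_c, stop_c = f.start_codon, f.stop_codon
            if (start_c is None or stop_c is None) and genome is not None:
                seq = extract_feature_sequence(genome, f).bases
                start_c = start_c or seq[:3]
                if stop_c is None:
                    stop_c = seq[-(len(seq) % 3 or 3):]
            profile.per_gene[name][f.name] = (start_c, stop_c)
            if start_c:
                starts[start_c] += 1
            else:
                profile.notes.append(f"{name}:{f.name} has no recorded start codon")
            if stop_c:
                stops[stop_c] += 1
        profile.start_freq[name] = starts
        profile.stop_freq[name] = stops
    return profile
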