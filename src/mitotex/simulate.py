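"""Synthetic circular mitogenomes and 75-bp transcriptome reads with truth.

The generator reproduces the geometry of a whitefly-type mitogenome (37 genes
plus two control regions on a 15,632 bp circle) with random sequence that
honors every annotated start codon, complete or partial stop codon, planted
codon contexts, planted control-region repeat arrays, and planted SNPs.
Reads are drawn from mature transcripts under the tRNA-punctuation model:
units are mono- or dicistronic, tRNAs are excised, and every transcript ends
in a poly(A) tail, so all downstream stages (depth, expression, poly(A)
junctions, cistron placement, SNP calling, repeat discovery) can be tested
against exact ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    AnnotationTable,
    GeneFeature,
    MitoGenome,
    NucleotideSequence,
    feature_length,
    reverse_complement,
)
from .mito_code import GeneticCode, INVERTEBRATE_MITO
from .cistrons import TranscriptionUnit, predict_units
from .expression import ReadAlignment

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "DEFAULT_ABUNDANCES",
    "generate_genome",
    "simulate_reads",
    "write_reads_fastq",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# Per-unit relative abundances ranked to mirror the observed expression
# ordering in whitefly mitochondria: rrnL far highest, nd3/rrnS lowest among
# the well-expressed coding units.  Genes in one unit share their abundance.
DEFAULT_ABUNDANCES: dict[str, float] = {
    "rrnL": 100.0,
    "cox2": 50.0,
    "cox1": 40.0,
    "atp8-atp6": 30.0,
    "nd1": 25.0,
    "cox3": 20.0,
    "nd6-cytb": 15.0,
    "nd4l-nd4": 10.0,
    "nd5": 8.0,
    "nd2": 6.0,
    "rrnS": 4.0,
    "nd3": 2.0,
}

DEFAULT_VARIANTS: list[tuple[int, str, float]] = [
    (800, "A", 1.0),   # cox1
    (3000, "C", 1.0),  # atp6
    (4500, "G", 1.0),  # nd5 (minus strand)
    (8000, "T", 1.0),  # cytb
    (15000, "C", 1.0),  # nd2
]

DEFAULT_REPEATS: list[tuple[int, int]] = [(44, 5), (169, 2)]


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the seed fixes every random draw."""

    seed: int = 0
    read_count: int = 100_000
    read_length: int = 75
    error_rate: float = 0.0
    tail_range: tuple[int, int] = (9, 40)
    abundances: dict[str, float] | None = None
    variants: list[tuple[int, str, float]] | None = None
    repeats: list[tuple[int, int]] | None = None
    codon_plants: list[tuple[str, int, str]] = field(default_factory=list)
    base_plants: dict[int, str] = field(default_factory=dict)
    genome_id: str = "synthetic_mitogenome"

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if self.tail_range[0] < 1 or self.tail_range[0] > self.tail_range[1]:
            raise ValueError("bad tail length range")


@dataclass
class SyntheticTruth:
    """Everything the simulator knows about the data it emitted."""

    genome: MitoGenome
    table: AnnotationTable
    units: list[TranscriptionUnit]
    abundances: dict[str, float]
    junctions: dict[str, int]  # unit id -> genome bp of the poly(A) junction
    variants: list[tuple[int, str, str, float]]  # pos, ref, alt, fraction
    repeats: list[tuple[int, int, int]]  # genome start, unit length, copies
    broken_codons: list[str] = field(default_factory=list)


def _med_layout() -> AnnotationTable:
    from .datasets import load_med_annotation

    return load_med_annotation()


def _reading_to_plus(f: GeneFeature, r: int) -> int:
    """Genome position of reading-strand offset ``r`` (1-based) in feature."""
    return f.start + r - 1 if f.strand == "+" else f.end - r + 1


def _write_reading(bases: list[str], f: GeneFeature, r_start: int, text: str, protected: set[int] | None = None) -> None:
    for i, ch in enumerate(text):
        pos = _reading_to_plus(f, r_start + i)
        bases[pos - 1] = ch if f.strand == "+" else ch.translate(_COMP)
        if protected is not None:
            protected.add(pos)


def _unit_span(table: AnnotationTable, unit: TranscriptionUnit) -> tuple[int, int]:
    feats = [table.get(m) for m in unit.members]
    return min(f.start for f in feats), max(f.end for f in feats)


def _unit_junction(table: AnnotationTable, unit: TranscriptionUnit) -> int:
    lo, hi = _unit_span(table, unit)
    return hi if unit.strand == "+" else lo


def generate_genome(config: SimulationConfig) -> tuple[MitoGenome, AnnotationTable, SyntheticTruth]:
    """Build a random genome on the fixed 37-gene layout, honoring codons.

    Imposition order on overlapping spans is: internal codons, planted codon
    contexts, stop codons, start codons, planted bases.  One annotated
    overlap (nd6 stop inside cytb start) is geometrically unsatisfiable; the
    loser is recorded in ``truth.broken_codons``.
    """
    rng = np.random.default_rng(config.seed)
    table = _med_layout()
    L = table.genome_length
    code = INVERTEBRATE_MITO
    bases = list("".join(np.array(list(_BASES))[rng.integers(0, 4, size=L)]))
    nonstop = [c for c in code.codon_to_aa if not code.is_stop(c)]
    protected: set[int] = set()

    # internal codons: everything between the start codon and the stop
    for f in table.pcgs:
        flen = feature_length(f, L)
        nc, rem = divmod(flen, 3)
        if f.stop_codon in {"TAA", "TAG"} and rem != 0:
            raise ValueError(f"{f.name}: complete stop but length not a codon multiple")
        last_internal = nc if f.stop_codon in {"T", "TA"} else nc - 1
        codons = rng.integers(0, len(nonstop), size=max(0, last_internal - 1))
        for k, ci in enumerate(codons, start=2):
            _write_reading(bases, f, (k - 1) * 3 + 1, nonstop[ci])
    # planted codon contexts (gene, 1-based codon index, codon)
    for gene, codon_idx, codon in config.codon_plants:
        f = table.get(gene)
        _write_reading(bases, f, (codon_idx - 1) * 3 + 1, codon, protected)
    # stop codons, then start codons (starts win the one impossible overlap)
    for f in table.pcgs:
        flen = feature_length(f, L)
        if f.stop_codon:
            _write_reading(bases, f, flen - len(f.stop_codon) + 1, f.stop_codon, protected)
    for f in table.pcgs:
        if f.start_codon:
            _write_reading(bases, f, 1, f.start_codon, protected)
    # planted tandem repeat arrays inside CR2
    repeats_cfg = DEFAULT_REPEATS if config.repeats is None else config.repeats
    repeats: list[tuple[int, int, int]] = []
    cr2 = table.get("CR2")
    cursor = cr2.start + 20
    for unit_len, copies in repeats_cfg:
        if cursor + unit_len * copies > cr2.end:
            raise ValueError("planted repeats exceed the control region")
        unit = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=unit_len)])
        for c in range(copies):
            for i, ch in enumerate(unit):
                bases[cursor - 1 + c * unit_len + i] = ch
        repeats.append((cursor, unit_len, copies))
        cursor += unit_len * copies + 15
    for pos, b in config.base_plants.items():
        bases[pos - 1] = b.upper()
        protected.add(pos)

    # guard base just downstream of every poly(A) junction: keep it non-A on
    # the reading strand so observed tails are never fully genome-templated
    units = predict_units(table)
    junctions: dict[str, int] = {}
    for unit in units:
        j = _unit_junction(table, unit)
        junctions[unit.unit_id] = j
        guard = j + 1 if unit.strand == "+" else j - 1
        guard = (guard - 1) % L + 1
        if guard not in protected:
            bases[guard - 1] = "C" if unit.strand == "+" else "G"

    # planted SNPs: alt expressed in reads only; genome keeps the reference
    variants_cfg = DEFAULT_VARIANTS if config.variants is None else config.variants
    variants: list[tuple[int, str, str, float]] = []
    for pos, alt, frac in variants_cfg:
        alt = alt.upper()
        if bases[pos - 1] == alt:
            if pos in protected:
                raise ValueError(f"planted variant at protected position {pos}")
            for b in _BASES:
                if b == alt:
                    continue
                bases[pos - 1] = b
                if _no_new_stop(bases, table, pos, code):
                    break
        variants.append((pos, bases[pos - 1], alt, frac))

    genome = MitoGenome(NucleotideSequence(config.genome_id, "".join(bases)))
    broken = _verify_codons(genome, table)
    truth = SyntheticTruth(
        genome=genome,
        table=table,
        units=units,
        abundances=dict(DEFAULT_ABUNDANCES if config.abundances is None else config.abundances),
        junctions=junctions,
        variants=variants,
        repeats=repeats,
        broken_codons=broken,
    )
    return genome, table, truth


def _no_new_stop(bases: list[str], table: AnnotationTable, pos: int, code: GeneticCode) -> bool:
    """True when the codon containing ``pos`` is not a stop in its gene frame."""
    from .genome_model import position_in_feature

    for f in table.pcgs:
        if f.contains(pos):
            pig = position_in_feature(pos, f)
            ci = (pig - 1) // 3
            start_r = ci * 3 + 1
            codon = "".join(
                bases[_reading_to_plus(f, start_r + i) - 1] for i in range(3)
            )
            if f.strand == "-":
                codon = codon.translate(_COMP)
            if code.is_stop(codon):
                return False
    return True


def _verify_codons(genome: MitoGenome, table: AnnotationTable) -> list[str]:
    from .genome_model import extract_feature_sequence

    broken = []
    for f in table.pcgs:
        seq = extract_feature_sequence(genome, f).bases
        if f.start_codon and seq[:3] != f.start_codon:
            broken.append(f"{f.name}:start")
        if f.stop_codon and seq[-len(f.stop_codon):] != f.stop_codon:
            broken.append(f"{f.name}:stop")
    return broken


def simulate_reads(
    config: SimulationConfig,
    truth: SyntheticTruth,
) -> tuple[list[tuple[str, str]], list[ReadAlignment], dict[str, str]]:
    """Draw reads from mature polyadenylated transcripts.

    Returns ``(reads, true_alignments, origins)`` where reads are
    ``(read_id, sequence)``, true alignments give each read body's genuine
    genome placement (tail recorded as clip), and origins maps read id to the
    transcription unit it was drawn from.  Strand-faithful single-end reads.
    """
    rng = np.random.default_rng(config.seed * 2 + 1)
    genome, table = truth.genome, truth.table
    rl = config.read_length
    t0, t1 = config.tail_range
    transcripts = []
    for unit in truth.units:
        w = truth.abundances.get(unit.unit_id, 0.0)
        if w <= 0:
            continue
        lo, hi = _unit_span(table, unit)
        body = genome.slice(lo, hi)
        if unit.strand == "-":
            body = reverse_complement(body)
        if len(body) + t0 < rl:
            import warnings

            warnings.warn(f"unit {unit.unit_id} shorter than the read length; skipped")
            continue
        # variants falling inside this unit's span, precomputed in body coords
        local_vars = []
        for pos, ref, alt, frac in truth.variants:
            if lo <= pos <= hi:
                off = pos - lo if unit.strand == "+" else hi - pos
                b = alt if unit.strand == "+" else alt.translate(_COMP)
                local_vars.append((off, b, frac))
        transcripts.append((unit, lo, hi, body, w, local_vars))
    if not transcripts:
        raise ValueError("no transcript has positive abundance")
    weights = np.array([t[4] for t in transcripts], dtype=float)
    probs = weights / weights.sum()
    n = config.read_count
    unit_idx = rng.choice(len(transcripts), size=n, p=probs)
    tails = rng.integers(t0, t1 + 1, size=n)
    u_start = rng.random(size=n)
    u_var = rng.random(size=n)
    do_err = config.error_rate > 0
    reads: list[tuple[str, str]] = []
    alignments: list[ReadAlignment] = []
    origins: dict[str, str] = {}
    for i in range(n):
        unit, lo, hi, body, _, local_vars = transcripts[unit_idx[i]]
        tail = int(tails[i])
        tlen = len(body) + tail
        off = int(u_start[i] * (tlen - rl + 1))
        body_part = max(0, min(rl, len(body) - off))
        seq = body[off : off + body_part] + "A" * (rl - body_part)
        if local_vars:
            chars = None
            for voff, vbase, vfrac in local_vars:
                k = voff - off
                if 0 <= k < body_part and (vfrac >= 1.0 or u_var[i] < vfrac):
                    if chars is None:
                        chars = list(seq)
                    chars[k] = vbase
            if chars is not None:
                seq = "".join(chars)
        if do_err:
            errs = rng.random(rl) < config.error_rate
            if errs.any():
                chars = list(seq)
                for k in np.nonzero(errs)[0]:
                    chars[k] = _BASES[(_BASES.index(chars[k]) + int(rng.integers(1, 4))) % 4]
                seq = "".join(chars)
        rid = f"r{i:07d}"
        reads.append((rid, seq))
        origins[rid] = unit.unit_id
        if body_part > 0:
            start = lo + off if unit.strand == "+" else hi - (off + body_part - 1)
            alignments.append(
                ReadAlignment(
                    read_id=rid,
                    start=start,
                    strand=unit.strand,
                    length=body_part,
                    clip=rl - body_part,
                )
            )
    return reads, alignments, origins


def write_reads_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
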