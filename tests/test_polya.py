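"""Poly(A) tail reads, junction assignment, stop completion, signal motifs."""

import numpy as np
import pytest

from mitotex.genome_model import (
    MitoGenome,
    NucleotideSequence,
    parse_annotation_text,
    reverse_complement,
)
from mitotex.polya import (
    DEFAULT_SIGNAL_MOTIFS,
    assign_polya_events,
    detect_tail_reads,
    find_polya_signals,
)


def _toy():
    """200 bp genome with a plus-strand gene at 21..80 ending in a partial T stop."""
    rng = np.random.default_rng(5)
    bases = list(rng.choice(list("ACGT"), size=200))
    bases[77:80] = list("GCT")  # gene tail ...T (partial stop)
    bases[80] = "C"  # guard: base after the junction is not A
    bases[95] = "C"  # guard for the downstream-junction read
    genome = MitoGenome(NucleotideSequence("toy", "".join(bases)))
    table = parse_annotation_text(
        "Gene\tStrand\tFrom\tTo\tLength\tStart\tStop\ng1\t+\t21\t80\t60\tATG\tT\n", 200
    )
    return genome, table


def test_detect_tail_reads_thresholds():
    reads = [
        ("ok", "ACGTACGT" + "A" * 10),
        ("short_tail", "ACGTACGT" + "A" * 8),
        ("t_tail", "T" * 10 + "ACGTACGT"),
        ("all_tail", "A" * 20),
    ]
    tails = {t.read_id: t for t in detect_tail_reads(reads, min_tail=9)}
    assert set(tails) == {"ok", "t_tail"}
    assert (tails["ok"].side, tails["ok"].tail_len, tails["ok"].body) == ("3A", 10, "ACGTACGT")
    assert (tails["t_tail"].side, tails["t_tail"].tail_base) == ("5T", "T")
    # 'more than eight' read as >= 8 is also supported
    assert "short_tail" in {t.read_id for t in detect_tail_reads(reads, min_tail=8)}


def test_junction_at_partial_stop_completes_to_taa():
    genome, table = _toy()
    read = ("r1", genome.slice(41, 80) + "A" * 12)
    events, dropped = assign_polya_events(detect_tail_reads([read]), genome, table)
    assert not dropped
    (e,) = events
    assert (e.junction, e.gene, e.offset_from_stop, e.completed_stop) == (80, "g1", 0, "TAA")


def test_junction_inside_cds_rejected():
    genome, table = _toy()
    read = ("r2", genome.slice(31, 70) + "A" * 12)
    events, dropped = assign_polya_events(detect_tail_reads([read]), genome, table)
    assert not events and dropped["no_gene"] == 1


def test_junction_downstream_in_spacer_accepted():
    genome, table = _toy()
    read = ("r3", genome.slice(56, 95) + "A" * 12)
    events, _ = assign_polya_events(detect_tail_reads([read]), genome, table)
    (e,) = events
    assert (e.junction, e.offset_from_stop, e.completed_stop) == (95, 15, None)


def test_antisense_t_tail_read_yields_same_event():
    genome, table = _toy()
    sense = genome.slice(41, 80) + "A" * 12
    antisense = reverse_complement(sense)
    events, _ = assign_polya_events(detect_tail_reads([("r", antisense)]), genome, table)
    (e,) = events
    assert (e.junction, e.gene, e.completed_stop, e.tail_base) == (80, "g1", "TAA", "T")


def test_strand_consistency_under_genome_mirror():
    """Reverse-complementing genome+annotation maps junctions through RC."""
    genome, table = _toy()
    L = genome.length
    mirrored = MitoGenome(NucleotideSequence("toy_rc", reverse_complement(genome.seq.bases)))
    table_rc = parse_annotation_text(
        f"Gene\tStrand\tFrom\tTo\tLength\tStart\tStop\ng1\t-\t{L - 80 + 1}\t{L - 21 + 1}\t60\tATG\tT\n", L
    )
    read = ("r1", genome.slice(41, 80) + "A" * 12)
    (e1,), _ = assign_polya_events(detect_tail_reads([read]), genome, table)
    (e2,), _ = assign_polya_events(detect_tail_reads([read]), mirrored, table_rc)
    assert e2.junction == L - e1.junction + 1
    assert (e2.gene, e2.offset_from_stop, e2.completed_stop) == (e1.gene, 0, "TAA")
    assert e2.strand == "-"


def test_templated_genomic_a_run_not_called_a_tail():
    rng = np.random.default_rng(6)
    bases = list(rng.choice(list("ACGT"), size=200))
    bases[80:92] = list("A" * 12)  # genomic A run
    genome = MitoGenome(NucleotideSequence("toy", "".join(bases)))
    table = parse_annotation_text("Gene\tStrand\tFrom\tTo\tStart\tStop\ng1\t+\t21\t80\tATG\tTAA\n", 200)
    read = ("r", genome.slice(41, 92))  # ends in the templated A run
    events, dropped = assign_polya_events(detect_tail_reads([read]), genome, table)
    assert not events and dropped["templated"] == 1


def test_polya_signal_window():
    genome, table = _toy()
    bases = list(genome.seq.bases)
    bases[54:60] = list("AATAAA")  # ends at 60; 20 bp upstream of junction 80
    bases[72:77] = list("AATAA")  # ends at 77; only 3 bp upstream: excluded
    genome2 = MitoGenome(NucleotideSequence("toy2", "".join(bases)))
    read = ("r1", genome2.slice(41, 80) + "A" * 12)
    (event,), _ = assign_polya_events(detect_tail_reads([read]), genome2, table)
    hits = find_polya_signals(genome2, event)
    assert any(h.motif == "AATAAA" and h.distance_upstream == 20 and h.position == 55 for h in hits)
    assert all(h.distance_upstream >= 8 for h in hits)


def test_no_signal_in_window_returns_empty():
    rng = np.random.default_rng(9)
    bases = "".join(rng.choice(list("CGT"), size=200))  # adenine-free genome
    genome = MitoGenome(NucleotideSequence("toy3", bases))
    table = parse_annotation_text("Gene\tStrand\tFrom\tTo\tStart\tStop\ng1\t+\t21\t80\tATG\tTAA\n", 200)
    read = ("r1", genome.slice(41, 80) + "A" * 12)
    (event,), _ = assign_polya_events(detect_tail_reads([read]), genome, table)
    assert find_polya_signals(genome, event) == []
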