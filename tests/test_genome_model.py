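"""Annotation model, coordinate arithmetic and annotation I/O."""

import pytest

from mitotex.genome_model import (
    AnnotationTable,
    GeneFeature,
    MitoGenome,
    NucleotideSequence,
    PCG,
    TRNA,
    RRNA,
    CONTROL_REGION,
    extract_feature_sequence,
    feature_length,
    intergenic_spacers,
    locate_position,
    overlaps,
    parse_annotation,
    parse_annotation_text,
    position_in_feature,
    reverse_complement,
)


def test_fixture_gene_census(med_table):
    """The published annotation carries 37 genes: 13 PCG + 22 tRNA + 2 rRNA."""
    genes = med_table.genes
    assert len(genes) == 37
    by_cat = {c: sum(1 for f in genes if f.category == c) for c in (PCG, TRNA, RRNA)}
    assert by_cat == {PCG: 13, TRNA: 22, RRNA: 2}
    assert len(med_table.by_category(CONTROL_REGION)) == 2


def test_parse_rejects_degenerate_inputs(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    with pytest.raises(ValueError):
        parse_annotation(empty, 100)
    out_of_range = "Gene\tStrand\tFrom\tTo\ng1\t+\t1\t300\n"
    with pytest.raises(ValueError, match="line 2"):
        parse_annotation_text(out_of_range, 100)


def test_parse_minimal_row():
    table = parse_annotation_text("Gene\tStrand\tFrom\tTo\ng1\t+\t1\t30\n", 100)
    assert len(table) == 1
    f = table.features[0]
    assert (f.category, f.start, f.end, f.strand) == (PCG, 1, 30, "+")


@pytest.mark.parametrize(
    "start,end,wraps,L,expected",
    [
        (3490, 5143, False, 15632, 1654),  # nd5 as printed
        (5, 5, False, 100, 1),
        (15630, 3, True, 15632, 6),  # positions 15630..15632,1..3
    ],
)
def test_feature_length(start, end, wraps, L, expected):
    f = GeneFeature("g", PCG, "+", start, end, wraps_origin=wraps)
    assert feature_length(f, L) == expected


def test_max_trna_length_is_78(med_table):
    assert max(feature_length(f, med_table.genome_length) for f in med_table.by_category(TRNA)) == 78


@pytest.mark.parametrize(
    "strand,start,end,wraps,expected",
    [
        ("+", 1, 3, False, "ATG"),
        ("-", 1, 3, False, "CAT"),
        ("+", 5, 2, True, "GAAT"),
    ],
)
def test_extract_feature_sequence(strand, start, end, wraps, expected):
    genome = MitoGenome(NucleotideSequence("g", "ATGCGA"))
    f = GeneFeature("f", PCG, strand, start, end, wraps_origin=wraps)
    assert extract_feature_sequence(genome, f).bases == expected


def test_extract_strand_flip_is_reverse_complement(med_fixture_genome):
    genome, table, _ = med_fixture_genome
    for f in table.pcgs[:4]:
        flipped = GeneFeature(f.name, f.category, "-" if f.strand == "+" else "+", f.start, f.end)
        assert extract_feature_sequence(genome, flipped).bases == reverse_complement(
            extract_feature_sequence(genome, f).bases
        )


def test_position_in_feature_matches_published_offsets(med_table):
    assert position_in_feature(5020, med_table.get("nd5")) == 124
    assert position_in_feature(1873, med_table.get("cox2")) == 271


def test_position_in_feature_termini(med_table):
    L = med_table.genome_length
    for f in med_table.features:
        flen = feature_length(f, L)
        head = f.start if f.strand == "+" else f.end
        tail = f.end if f.strand == "+" else f.start
        assert position_in_feature(head, f, L) == 1
        assert position_in_feature(tail, f, L) == flen
    with pytest.raises(ValueError):
        position_in_feature(2350, med_table.get("atp8"))


def test_locate_position(med_table):
    assert [f.name for f in locate_position(984, med_table)] == ["cox1"]
    hits = locate_position(14011, med_table)
    assert [f.category for f in hits] == [CONTROL_REGION]
    assert locate_position(2350, med_table) == []  # tRNA-Lys..atp8 spacer


def test_spacers_from_published_coordinates(med_table):
    spacers = intergenic_spacers(med_table, min_len=10)
    lengths = {sp.flanking: sp.length for sp in spacers}
    assert lengths[("tRNA-LysAAR", "atp8")] == 25  # 2360 - 2334 - 1
    assert lengths[("cox3", "tRNA-IleAUN")] == 973  # this interval is CR2
    assert len(spacers) == 9
    # rrnS -> tRNA-Gln gap is 9 bp under the bases convention, 10 coord-diff
    assert ("tRNA-GlnCAR", "rrnS") not in lengths
    coord = {sp.flanking: sp.length for sp in intergenic_spacers(med_table, convention="coord-diff")}
    assert coord[("tRNA-GlnCAR", "rrnS")] == 10


def test_adjacent_features_leave_no_spacer():
    table = parse_annotation_text(
        "Gene\tStrand\tFrom\tTo\ng1\t+\t1\t50\ng2\t+\t51\t100\n", 100
    )
    assert intergenic_spacers(table, min_len=1) == []


def test_features_plus_spacers_tile_the_circle(med_table):
    L = med_table.genome_length
    covered = [False] * (L + 1)
    for f in med_table.features:
        for p in range(f.start, f.end + 1):
            covered[p] = True
    for sp in intergenic_spacers(med_table, min_len=1, include_control_regions=True):
        for p in range(sp.start, sp.end + 1):
            assert not any(f.contains(p) for f in med_table.features)
            covered[p] = True
    assert all(covered[1:])


def test_overlaps_follow_table_coordinates(med_table):
    shared = {frozenset((a, b)): n for a, b, n in overlaps(med_table)}
    assert shared[frozenset(("atp8", "atp6"))] == 11
    assert shared[frozenset(("nd4", "nd4l"))] == 4
    assert frozenset(("cox1", "cox2")) not in shared


def test_annotation_roundtrip_is_bit_exact(med_table, tmp_path):
    path = tmp_path / "ann.tsv"
    text = med_table.to_tsv(path)
    reparsed = parse_annotation(path, med_table.genome_length)
    assert reparsed.to_tsv() == text
    gff = tmp_path / "ann.gff3"
    med_table.to_gff3(gff)
    from_gff = parse_annotation(gff, med_table.genome_length)
    assert from_gff.to_tsv() == text


def test_annotation_table_validation():
    f = GeneFeature("g1", PCG, "+", 1, 30)
    with pytest.raises(ValueError, match="duplicate"):
        AnnotationTable(100, [f, GeneFeature("g1", PCG, "+", 40, 60)])
    with pytest.raises(ValueError, match="exceed"):
        AnnotationTable(20, [f])
    with pytest.raises(ValueError):
        GeneFeature("g", PCG, "+", 10, 5)  # start > end without wrap
    with pytest.raises(ValueError):
        GeneFeature("g", PCG, "+", 1, 9, stop_codon="TGA")  # not a table-5 stop
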