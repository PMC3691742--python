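"""Pileup, depth-filtered SNP calling, and codon-level annotation."""

import numpy as np
import pytest

from mitotex.expression import ReadAlignment
from mitotex.genome_model import MitoGenome, NucleotideSequence, reverse_complement
from mitotex.mapper import map_reads
from mitotex.mito_code import INVERTEBRATE_MITO as CODE, translate
from mitotex.variants import (
    PileupColumn,
    annotate_variant,
    build_pileup,
    call_snps,
    write_variant_table,
    write_vcf,
)

rng = np.random.default_rng(21)
GENOME = MitoGenome(NucleotideSequence("g", "".join(rng.choice(list("ACGT"), size=400))))


def _aln(start, seq, rid="r", strand="+"):
    return ReadAlignment(read_id=rid, start=start, strand=strand, length=len(seq), seq=seq)


def test_pileup_counts_and_coverage():
    ref = GENOME.slice(50, 79)
    alt = "T" if ref[10] != "T" else "G"
    reads = [_aln(50, ref[:10] + alt + ref[11:], rid=f"r{i}") for i in range(12)]
    pileup = build_pileup(reads, GENOME)
    col = next(c for c in pileup if c.position == 60)
    assert col.depth == 12 and col.counts[alt] == 12
    assert all(50 <= c.position <= 79 for c in pileup)  # uncovered positions absent


def test_minus_strand_bases_complemented_via_mapper():
    body = GENOME.slice(100, 139)
    alns, _ = map_reads([("rc", reverse_complement(body))], GENOME)
    pileup = build_pileup(alns, GENOME)
    for col in pileup:
        assert col.counts[GENOME.base(col.position)] == 1


@pytest.mark.parametrize(
    "depth,alt_n,called",
    [(12, 12, True), (9, 9, False), (50, 1, False)],
)
def test_call_snps_thresholds(depth, alt_n, called):
    ref = GENOME.base(200)
    alt = "A" if ref != "A" else "C"
    counts = {b: 0 for b in "ACGT"}
    counts[ref] = depth - alt_n
    counts[alt] = alt_n
    col = PileupColumn(position=200, ref=ref, counts=counts)
    calls = call_snps([col], min_depth=10, min_alt_frac=0.2)
    assert bool(calls) is called


def test_calls_respect_depth_filter_soundness(sim_run):
    pileup_by_pos = {c.position: c for c in sim_run["pileup"]}
    for pos, ref, alt, depth, frac in sim_run["calls"]:
        assert pileup_by_pos[pos].depth >= 10
        assert depth == pileup_by_pos[pos].depth


def test_annotate_reproduces_published_snp_table(med_fixture_genome, med_snps):
    """All 8 published SNPs: gene, offset, codon change and aa change match."""
    genome, table, _ = med_fixture_genome
    coding = missense = in_pcg = 0
    for _, row in med_snps.iterrows():
        call = annotate_variant(int(row["Pos"]), row["Ref"], row["Alt"], genome, table, CODE)
        if row["Gene_name"] == "CR region":
            assert call.gene == "CR region" and call.effect == "noncoding"
            assert call.ref_codon is None
            continue
        coding += 1
        in_pcg += 1
        assert call.gene == row["Gene_name"]
        assert call.strand == row["Strand"]
        assert call.position_in_gene == int(row["SNP_position_in_gene"])
        assert call.ref_codon == row["Three_base_ref"]
        assert call.alt_codon == row["Three_base_alt"]
        assert call.ref_aa == row["aa_ref"]
        assert call.alt_aa == row["aa_alt"]
        if call.effect == "missense":
            missense += 1
    assert coding == 5 and missense == 2 and in_pcg == 5


def test_annotate_validates_reference(med_fixture_genome):
    genome, table, _ = med_fixture_genome
    ref = genome.base(984)
    wrong = "A" if ref != "A" else "C"
    with pytest.raises(ValueError, match="mismatch"):
        annotate_variant(984, wrong, "G", genome, table, CODE)


def test_effect_agrees_with_translation_oracle(med_fixture_genome):
    """Random coding SNPs: effect == (translate(ref codon) != translate(alt))."""
    genome, table, _ = med_fixture_genome
    local = np.random.default_rng(8)
    pcgs = table.pcgs
    for _ in range(60):
        f = pcgs[int(local.integers(len(pcgs)))]
        pos = int(local.integers(f.start + 3, f.end - 3))
        ref = genome.base(pos)
        alt = "ACGT".replace(ref, "")[int(local.integers(3))]
        call = annotate_variant(pos, ref, alt, genome, table, CODE)
        if call.ref_codon is None:
            continue
        same = translate(call.ref_codon, CODE) == translate(call.alt_codon, CODE)
        assert (call.effect == "synonymous") is same


def test_vcf_and_table_outputs(tmp_path, med_fixture_genome):
    genome, table, _ = med_fixture_genome
    calls = [annotate_variant(984, genome.base(984), "A", genome, table, CODE, depth=15, alt_frac=0.9)]
    vcf_path = tmp_path / "out.vcf"
    write_vcf(calls, genome, vcf_path)
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vcf:
        rec = next(iter(vcf))
        assert rec.pos == 984 and rec.alts == ("A",)
        assert rec.info["GENE"] == "cox1"
    tsv_path = tmp_path / "out.tsv"
    write_variant_table(calls, tsv_path)
    assert "cox1" in tsv_path.read_text()
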