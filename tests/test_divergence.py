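"""Ortholog alignment, partitioned divergence, Nei-Gojobori Ka/Ks, skews."""

import math
import warnings
from itertools import permutations

import numpy as np
import pytest

from mitotex.divergence import (
    AlignedPair,
    align_orthologs,
    ka_ks,
    partition_divergence,
    skew,
)
from mitotex.mito_code import INVERTEBRATE_MITO as CODE


# --------------------------------------------------------------------------
# alignment


def test_align_identical_sequences_has_no_gaps():
    pair = align_orthologs("ATGAAACCT", "ATGAAACCT")
    assert pair.seq_a == pair.seq_b == "ATGAAACCT"


def test_align_single_mismatch():
    pair = align_orthologs("ATGAAA", "ATGAAG")
    assert len(pair.seq_a) == 6
    assert sum(a != b for a, b in zip(pair.seq_a, pair.seq_b)) == 1


def test_align_inserted_codon_yields_codon_sized_gap():
    pair = align_orthologs("ATGAAACCTGGT", "ATGAAATTTCCTGGT")
    assert pair.seq_a == "ATGAAA---CCTGGT"
    assert pair.seq_b == "ATGAAATTTCCTGGT"


def test_align_rejects_empty():
    with pytest.raises(ValueError):
        align_orthologs("", "ATG")


# --------------------------------------------------------------------------
# partitioned divergence


def test_partition_identical_pair_is_zero_everywhere():
    rep = partition_divergence(AlignedPair("g", "ATGCGA", "ATGCGA"), CODE)
    for cell in rep.cells.values():
        assert cell.pct in (None, 0.0)


def test_partition_single_transition():
    rep = partition_divergence(AlignedPair("g", "ATGAAA", "ATGAAG"), CODE)
    cell = rep.cell("all", "all")
    assert cell.pct == pytest.approx(100 / 6)
    assert (cell.transitions, cell.transversions) == (1, 0)
    assert cell.se == pytest.approx(math.sqrt((1 / 6) * (5 / 6) / 6))
    assert cell.compared_kb == pytest.approx(0.006)


def test_partition_symmetry_and_site_accounting():
    rng = np.random.default_rng(7)
    bases = "ACGT"
    a = "".join(rng.choice(list(bases), size=300))
    b = "".join(
        c if rng.random() > 0.2 else bases[(bases.index(c) + rng.integers(1, 4)) % 4] for c in a
    )
    fwd = partition_divergence(AlignedPair("g", a, b), CODE)
    # symmetric in difference counts (classes use the first sequence, so
    # compare the class-agnostic cell)
    rev = partition_divergence(AlignedPair("g", b, a), CODE)
    assert fwd.cell("all", "all").n_diff == rev.cell("all", "all").n_diff
    for cls in ("all", "nd", "4d"):
        full, cpg, non = (fwd.cell(cls, c) for c in ("all", "CpG", "nonCpG"))
        assert full.n_sites == cpg.n_sites + non.n_sites
        assert full.n_diff == cpg.n_diff + non.n_diff
        if full.n_sites:
            weighted = (
                (cpg.pct or 0) * cpg.n_sites + (non.pct or 0) * non.n_sites
            ) / full.n_sites
            assert full.pct == pytest.approx(weighted)
    assert (
        fwd.cell("nd", "all").n_sites + fwd.cell("4d", "all").n_sites
        <= fwd.cell("all", "all").n_sites
    )


def test_partition_empty_cell_reports_none():
    # AT-only sequences contain no CpG context at all
    rep = partition_divergence(AlignedPair("g", "ATTAAA", "ATTAAA"), CODE)
    assert rep.cell("all", "CpG").n_sites == 0
    assert rep.cell("all", "CpG").pct is None


# --------------------------------------------------------------------------
# Nei-Gojobori


def _oracle_ng(a, b):
    """Independent brute-force Nei-Gojobori oracle (Biopython translation).

    Counts synonymous sites per codon from the three possible substitutions
    and averages pathway difference counts over all orderings; a step is
    synonymous iff it preserves a non-stop amino acid; Jukes-Cantor applied.
    """
    from Bio.Seq import Seq

    aa = lambda c: str(Seq(c).translate(table=5))
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca + cb or aa(ca) == "*" or aa(cb) == "*":
            continue
        for codon in (ca, cb):
            syn = 0
            for pos in range(3):
                for base in "ACGT":
                    if base != codon[pos]:
                        alt = codon[:pos] + base + codon[pos + 1 :]
                        if aa(alt) == aa(codon) and aa(codon) != "*":
                            syn += 1
            S += syn / 6.0  # /3 per site, averaged over the two codons
        N += 3.0 - sum(
            sum(
                aa(c[:p] + x + c[p + 1 :]) == aa(c) and aa(c) != "*"
                for x in "ACGT"
                if x != c[p]
            )
            / 3.0
            for c in (ca, cb)
            for p in range(3)
        ) / 2.0
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if diffs:
            paths = list(permutations(diffs))
            s_tot = n_tot = 0.0
            for path in paths:
                cur = ca
                for p in path:
                    nxt = cur[:p] + cb[p] + cur[p + 1 :]
                    if aa(cur) == aa(nxt) and aa(cur) != "*":
                        s_tot += 1
                    else:
                        n_tot += 1
                    cur = nxt
            Sd += s_tot / len(paths)
            Nd += n_tot / len(paths)

    def jc(p):
        return None if p >= 0.75 - 1e-9 else -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(Sd / S) if S else None
    ka = jc(Nd / N) if N else None
    return ka, ks


def test_ka_ks_matches_brute_force_oracle_on_random_pairs():
    """200 random pairs of up to 10 codons, agreement to 1e-9."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    checked = 0
    for _ in range(200):
        n = int(rng.integers(1, 11))
        a = "".join(rng.choice(list(bases), size=3 * n))
        b = "".join(
            c if rng.random() > 0.25 else bases[(bases.index(c) + rng.integers(1, 4)) % 4]
            for c in a
        )
        mine = ka_ks(AlignedPair("r", a, b), CODE)
        oka, oks = _oracle_ng(a, b)
        for x, y in ((mine.ka, oka), (mine.ks, oks)):
            if x is None or y is None:
                assert x == y
            else:
                assert abs(x - y) < 1e-9
                checked += 1
    assert checked > 100  # most draws exercise the defined branch


def test_ka_ks_matches_biopython_ng86():
    """Independent cross-check against Bio.codonalign on a stop-free pair."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from Bio.Data import CodonTable

    a, b = "ATGAAACCTGGTGTTCATTTACGA", "ATGAAGCCTGGTATTCATTTACGA"
    mine = ka_ks(align_orthologs(a, b), CODE)
    dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86",
                       codon_table=CodonTable.unambiguous_dna_by_id[5])
    assert mine.ka == pytest.approx(dn, abs=1e-12)
    assert mine.ks == pytest.approx(ds, abs=1e-12)
    assert mine.ratio == pytest.approx(dn / ds)


def test_ka_ks_degenerate_cases():
    same = ka_ks(AlignedPair("g", "ATGAAA", "ATGAAA"), CODE)
    assert (same.ka, same.ks) == (0.0, 0.0)
    assert same.ratio is None  # 0/0 undefined
    # single synonymous difference: no nonsynonymous change counted
    syn = ka_ks(AlignedPair("g", "ATGAAA", "ATGAAG"), CODE)
    assert syn.ka == 0.0 and syn.n_diff == 0.0
    # defined Ks with zero Ka gives ratio exactly 0
    longer = ka_ks(align_orthologs("ATGAAACCTGGTCAT", "ATGAAGCCTGGTCAT"), CODE)
    assert longer.ka == 0.0 and longer.ks > 0 and longer.ratio == 0.0


# --------------------------------------------------------------------------
# skews


def test_skew_examples():
    assert skew("AAAT").at_skew == pytest.approx(0.5)
    assert skew("GGCC").gc_skew == 0.0
    assert skew("GGCC").at_skew is None
    with pytest.raises(ValueError):
        skew("")


def test_skew_bounds_on_random_sequences():
    rng = np.random.default_rng(3)
    for _ in range(20):
        s = "".join(rng.choice(list("ACGT"), size=50))
        r = skew(s)
        for value in (r.at_skew, r.gc_skew):
            if value is not None:
                assert -1.0 <= value <= 1.0
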