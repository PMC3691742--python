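import pytest

from mitotex.datasets import load_med_annotation, load_med_snps, med_like_genome
from mitotex.simulate import SimulationConfig, generate_genome, simulate_reads


@pytest.fixture(scope="session")
def med_table():
    return load_med_annotation()


@pytest.fixture(scope="session")
def med_snps():
    return load_med_snps()


@pytest.fixture(scope="session")
def med_fixture_genome():
    """Synthetic genome on the published layout with published SNP codons."""
    return med_like_genome(seed=0)


@pytest.fixture(scope="session")
def sim_run():
    """One full default simulation (100k error-free 75-bp reads) with all
    downstream stages computed once; shared by the end-to-end tests."""
    from mitotex.mapper import map_reads
    from mitotex.expression import expression_levels
    from mitotex.polya import detect_tail_reads, assign_polya_events
    from mitotex.variants import build_pileup, call_snps

    config = SimulationConfig(seed=1)
    genome, table, truth = generate_genome(config)
    reads, true_alignments, origins = simulate_reads(config, truth)
    alignments, stats = map_reads(reads, genome)
    tails = detect_tail_reads(reads, min_tail=9)
    events, dropped = assign_polya_events(tails, genome, table)
    pileup = build_pileup(alignments, genome)
    calls = call_snps(pileup)
    return {
        "config": config,
        "genome": genome,
        "table": table,
        "truth": truth,
        "reads": reads,
        "true_alignments": true_alignments,
        "origins": origins,
        "alignments": alignments,
        "map_stats": stats,
        "tails": tails,
        "events": events,
        "dropped": dropped,
        "pileup": pileup,
        "calls": calls,
    }
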