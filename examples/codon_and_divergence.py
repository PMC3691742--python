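"""Codon usage, site degeneracy and Ka/Ks between two diverged gene sets.

Builds a synthetic mitogenome, reports codon usage over its 13 PCGs, then
derives a 'diverged ortholog' of each gene by mutating ~8% of sites (with a
2:1 transition bias) and reports Nei-Gojobori Ka/Ks and divergence
partitioned by site degeneracy and CpG context.
"""

import numpy as np

from mitotex.datasets import med_like_genome
from mitotex.divergence import align_orthologs, ka_ks, partition_divergence, skew
from mitotex.genome_model import extract_feature_sequence
from mitotex.mito_code import INVERTEBRATE_MITO as code, codon_usage

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

genome, table, _ = med_like_genome(seed=0)

usage = codon_usage([extract_feature_sequence(genome, f) for f in table.pcgs], code)
top = sorted(usage.counts.items(), key=lambda kv: -kv[1])[:4]
print("four most frequent codons over the 13 PCGs:")
for codon, count in top:
    print(f"  {codon} ({code.aa(codon)}): {count}")

sk = skew(genome.seq)
print(f"\nwhole-genome AT skew {sk.at_skew:+.3f}, GC skew {sk.gc_skew:+.3f}")


def mutate(seq: str, rng, rate=0.08) -> str:
    out = []
    for b in seq:
        if rng.random() < rate:
            if rng.random() < 2 / 3:  # transitions twice as likely
                out.append(TRANSITION[b])
            else:
                out.append(rng.choice([x for x in "ACGT" if x != b and x != TRANSITION[b]]))
        else:
            out.append(b)
    return "".join(out)


rng = np.random.default_rng(17)
print("\nper-gene Ka/Ks against an 8%-mutated ortholog (neutral mutation, so")
print("Ka/Ks should sit near 1 -- real PCGs under purifying selection show << 1):")
pairs = []
for f in table.pcgs[:5]:
    cds_a = extract_feature_sequence(genome, f).bases
    pair = align_orthologs(cds_a, mutate(cds_a, rng), code, gene=f.name)
    pairs.append(pair)
    r = ka_ks(pair, code)
    ratio = "undef" if r.ratio is None else f"{r.ratio:.3f}"
    print(f"  {f.name}: Ka={r.ka:.4f} Ks={r.ks:.4f} Ka/Ks={ratio}")

rep = partition_divergence(pairs, code)
print("\ndivergence partitioned by degeneracy class (pooled over the genes):")
for cls in ("all", "nd", "4d"):
    c = rep.cell(cls, "all")
    print(f"  {cls:>3} sites: {c.pct:.2f}% difference over {c.compared_kb:.2f} kb, Ts/Tv="
          f"{'undef' if c.ts_tv is None else f'{c.ts_tv:.2f}'}")
print("\nIn real orthologs the fourfold-degenerate (4d) partition diverges far")
print("faster than the nondegenerate (nd) one; uniform mutation erases that gap.")
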