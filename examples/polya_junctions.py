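"""Detect poly(A) junctions and the completion of partial stop codons.

Simulated reads that run off a transcript's 3' end carry part of the poly(A)
tail; trimming the tail and mapping the body locates the polyadenylation
junction.  Genes annotated with a partial stop (T) have it completed to TAA
by the first two tail adenosines.
"""

from collections import Counter

from mitotex.polya import assign_polya_events, detect_tail_reads, find_polya_signals
from mitotex.simulate import SimulationConfig, generate_genome, simulate_reads

config = SimulationConfig(seed=11, read_count=20_000)
genome, table, truth = generate_genome(config)
reads, _, _ = simulate_reads(config, truth)

tails = detect_tail_reads(reads, min_tail=9)  # "more than eight continuous A or T"
print(f"{len(tails)} of {len(reads)} reads carry a terminal run of >= 9 nt")

events, dropped = assign_polya_events(tails, genome, table)
print(f"{len(events)} poly(A) events placed ({dict(dropped) or 'none dropped'})\n")

by_gene = Counter((e.gene, e.junction, e.completed_stop) for e in events)
print(f"{'gene':>6} {'junction':>8} {'reads':>6}  completed stop")
for (gene, junction, completed), n in sorted(by_gene.items(), key=lambda kv: kv[0][1]):
    print(f"{gene:>6} {junction:>8} {n:>6}  {completed or '-'}")

event = next(e for e in events if e.gene == "cox1")
signals = find_polya_signals(genome, event)
print(f"\npoly(A)-signal motifs 8-229 bp upstream of the cox1 junction: "
      f"{[(s.motif, s.distance_upstream) for s in signals[:3]] or 'none (random sequence)'}")
print("cox1, cox2 and nd5 end in a bare T; the TAA above is tail-completed.")
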