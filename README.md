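# mitotex

Analytics for circular insect mitochondrial genomes and their transcriptomes,
built around the mitogenome of the Mediterranean (MED) species of the
*Bemisia tabaci* whitefly complex: a 15,632 bp circle encoding 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and two putative control
regions. The package is aimed at researchers who have a mitogenome
annotation and RNA-seq reads (or alignments) and want the classic battery of
mitogenomic analyses as a tested, scriptable library rather than a chain of
one-off tools.

## What it computes

- **Annotation analytics** — gene lengths, strand layout, inclusive-coordinate
  gene overlaps, and intergenic spacers on the circle (1-based, fully
  inclusive coordinates throughout; wrap-around features supported).
- **Codon analytics under the invertebrate mitochondrial code** (NCBI table 5:
  ATA=Met, AGA/AGG=Ser, TGA=Trp) — translation, codon usage and RSCU
  (RSCU_c = n_c · |family| / Σ family), site-degeneracy classes
  (nondegenerate *nd*: every substitution changes the amino acid; fourfold
  *4d*: none does), and completion of genome-encoded partial stop codons
  (T/TA → TAA) by polyadenylation.
- **Pairwise divergence** — protein-guided codon-aware ortholog alignment,
  percent difference partitioned by {all, nd, 4d} × {all, CpG, non-CpG}
  with binomial SE and Ts/Tv, Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor
  correction (d = −¾ ln(1 − 4p/3)), and strand skews
  AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C).
- **Expression from reads** — per-base depth (circular), reads-per-base
  expression per gene/control region/spacer, and 2^−ΔΔCt fold change.
- **Poly(A) analysis** — reads with a terminal run of ≥ 9 A (or a leading T
  run on antisense reports) are trimmed and placed; the junction (last
  transcribed base) is located relative to stop codons, partial stops are
  completed to TAA, and poly(A) signal motifs (AATAAA family) are scanned
  8–229 bp upstream.
- **tRNA-punctuation transcription units** — PCG/rRNA genes contiguous on a
  strand with no intervening same-strand tRNA (and no control region) form
  one mature transcript; contigs can be placed onto the genome to verify
  dicistrons.
- **SNP calling and annotation** — pileup from ungapped alignments, calls at
  depth ≥ 10 with an alt-fraction filter, codon/amino-acid annotation with
  minus-strand alleles complemented onto the reading strand; TSV and VCF
  v4.2 output.
- **Control regions** — tandem repeat arrays (mismatch-tolerant), regulatory
  motifs (polyT, TATA, G[A]nT, TA(A)n-like, mTERF consensus ACTAA) and
  exact inverted repeats (stem-loops).
- **Synthetic data with full truth** — a generator that reproduces the
  37-gene layout with random sequence honoring every annotated codon, plants
  repeats/SNPs, and draws 75-bp single-end reads from mature polyadenylated
  transcripts, so the whole pipeline is testable offline.

The published annotation (Table-style TSV) and SNP table are packaged as
fixtures; the deposited genome sequences are not redistributed, so
sequence-dependent analyses run on synthetic genomes that honor the
published coordinates and codon contexts.

## Worked example

```bash
python examples/polya_junctions.py
```

prints (seed 11, 20,000 simulated reads):

```
371 of 20000 reads carry a terminal run of >= 9 nt
370 poly(A) events placed ({'templated': 1})

  gene junction  reads  completed stop
  cox1     1537     25  TAA
  cox2     2266     94  TAA
  atp6     3233     37  -
   nd5     3490      7  TAA
  ...
```

Each line is one polyadenylation site: the junction is the genome coordinate
of the last transcribed base (1537 is the annotated end of *cox1*), the read
count is how many tailed reads support it, and `TAA` marks genes whose
genome-encoded partial stop (a bare `T` in *cox1*, *cox2*, *nd5*) is
completed by the first two adenosines of the tail. The other examples cover
annotation statistics, codon usage + Ka/Ks, expression profiling, SNP
calling and control-region structure, each printing a short interpretation.

A thin CLI wraps the same library:

```bash
mitotex simulate --seed 7 --reads 50000 --out sim/
mitotex run --config pipeline.yaml     # stages: annotate, expression, polya, snps, ...
mitotex annotate-stats --annotation sim/annotation.tsv --genome-length 15632
```

## Layout

```
src/mitotex/        library (genome_model, mito_code, divergence, expression,
                    mapper, polya, cistrons, variants, control_region,
                    simulate, datasets, pipeline, cli)
examples/           runnable narrative scripts, one per capability
tests/              pytest suite incl. end-to-end simulation checks
docs/methods.md     models, conventions, defaults and limitations
```
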