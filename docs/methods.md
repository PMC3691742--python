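# Methods

## Coordinate model

All coordinates are 1-based and fully inclusive, matching published insect
mitogenome annotation tables; GFF3 export uses the same convention natively.
The genome is circular: position arithmetic is modulo the length L, at most
one feature may wrap the origin, and spans given as `start > end` denote
wrap-around. Overlap sizes are inclusive interval intersections (features
`a..b` and `b..c` share 1 bp). Intergenic spacer length defaults to the
count of unannotated bases, `next.start − prev.end − 1` (`coord-diff`,
i.e. `next.start − prev.end`, is available); under this convention the
packaged annotation yields 9 spacers of ≥ 10 bp, with the rrnS→tRNA-Gln gap
at 9 bp falling just below the cutoff. The two control regions are explicit
features (CR1 between *rrnS* and *tRNA-Asn*, CR2 between *cox3* and
*tRNA-Ile*), but they are treated as unannotated when spacers are
enumerated, so they also surface as the two largest spacers.

The packaged annotation reproduces the published table verbatim, including a
printed *nd6* length (547) that disagrees with its own coordinates
(6943..7389 → 447) and two tRNA lengths (57, 62) outside the stated 63–78 bp
range; the parser trusts coordinates and recomputes all lengths.

## Genetic code and degeneracy

The default code is NCBI translation table 5 (invertebrate mitochondrial),
taken from Biopython's codon tables; any table id can be selected. A codon
position is *fourfold degenerate* when all three substitutions preserve the
amino acid and *nondegenerate* when all three change it, a change to or from
a stop counting as a change; one preserving substitution is twofold, two are
"other" (threefold). Note that under table 5 the AGN box is entirely serine,
so AGA/AGG third positions are fourfold. Stop codons and codons containing
ambiguous bases classify as "other" and are excluded from both partitions —
the nd and 4d site counts therefore do not sum to the total.

Codon usage counts include stop codons (they form their own synonymous
family) and skip trailing partial codons and codons containing N. RSCU is
count × family size / family total, defined only for observed families.
Codon usage counts only genome-encoded complete codons; the
polyadenylation-completed stops of *cox1*/*cox2*/*nd5* are not counted.

## Divergence and Ka/Ks

Ortholog pairs are aligned by translating both CDS (trimmed to complete
codons), aligning the proteins globally (identity-flavored scoring: match 2,
mismatch −1, gap open −5, extend −1) and projecting the alignment back onto
codons, so gaps come in multiples of 3 and the frame anchors at column 1.

Divergence is tabulated over {all, nd, 4d} × {all, CpG, non-CpG} cells.
Site class and CpG context are classified on the first (reference) sequence:
a site is CpG-context when its base is the C of a CG dinucleotide or the G
preceded by C on the coding strand, looking through alignment gaps. Each
cell reports compared sites, percent difference, an analytic binomial
standard error sqrt(p(1−p)/n), compared kb, and Ts/Tv over the differing
columns (undefined when no transversion occurs). Cells with zero compared
sites report empty, not zero.

Ka/Ks uses Nei–Gojobori (1986) equal-weight counting: synonymous site
content per codon is the fraction of the nine possible single-base changes
that preserve the amino acid (averaged over the two sequences), and
difference counts average over all orderings of multi-position codon
differences. A mutational step is synonymous iff it preserves a non-stop
amino acid; codon columns containing gaps, ambiguity or a stop codon in
either sequence are excluded. The Jukes–Cantor correction
d = −¾ ln(1 − 4p/3) is undefined for p ≥ 3/4 (a 1e-9 tolerance keeps
proportions landing exactly on the boundary deterministically undefined);
the ratio is undefined when Ks is 0 or either rate is undefined. The
implementation agrees exactly with Biopython's `cal_dn_ds(method="NG86")`
on stop-free pairs, which serves as an independent cross-check in the test
suite alongside a brute-force enumerative oracle.

## Read mapping (internal)

A k-mer (k = 20) seed index of the doubled genome supports both strands and
origin-spanning reads; candidate placements are verified base-by-base with a
mismatch bound (default 2), and reads with more than one best placement are
dropped as ambiguous. Terminal 3' A runs and 5' T runs of any length are
soft-clipped before placement: a read ending a few bases into a poly(A) tail
is indistinguishable from one ending in a templated A run, and leaving those
bases in scatters systematic mismatches immediately downstream of poly(A)
junctions (observed as spurious SNP calls in simulation). The clipped length
is recorded; stored alignment sequences are plus-strand oriented. This
matcher is sized for a ~16 kb circle; it is exact-match-with-mismatches, not
splice- or indel-aware.

## Expression

Expression is reads-per-base: mapped reads overlapping a feature by at least
1 bp (configurable) divided by feature length. A read overlapping two
features (overlapping genes, dicistronic junctions) counts toward both by
default; a `majority` mode assigns it only to the feature with the largest
overlap. Depth uses the full aligned span with no quality weighting, and the
depth profile conserves total aligned bases. qPCR relative expression is
2^−ΔΔCt.

## Poly(A) junctions

Tail reads are those with a terminal base run ≥ 9 nt, reading the published
filter "more than eight continuous A or T" as strict; the threshold is a
parameter (≥ 8 is equally supported). A 5' T run marks the antisense report
of a poly(A) read; its body is reverse-complemented into transcript
orientation before placement. After mapping the body, the genomic A run
immediately downstream of the body end is treated as templated: the junction
extends over it and it is deducted from the tail, and events whose remaining
tail is < 2 nt are dropped as fully templated. An event is assigned to the
nearest same-strand PCG/rRNA whose final stop-codon base lies at most 60 bp
(default) upstream of the junction; junctions strictly inside a CDS upstream
of every admissible stop are rejected. PCGs with annotated partial stops
(T/TA) whose junction falls exactly at the final encoded base report the
tail-completed stop TAA. Signal motifs (default AATAAA, ATTAAA, TATAAA,
AATAA — the canonical signal and its common single-substitution variants)
are scanned on the reading strand 8–229 bp upstream of the junction,
distance measured from the motif's last base.

## Transcription units

Separators are same-strand tRNAs (an opposite-strand tRNA belongs to the
other primary transcript) and control regions on either strand. PCG/rRNA
genes between separators form one unit when consecutive members are within
50 bp (all three known whitefly dicistron pairs actually overlap); the
tolerance is a parameter. On the packaged annotation this yields 12 units:
three dicistrons (*atp8*–*atp6*, *nd4l*–*nd4*, *nd6*–*cytb*) and nine
monocistronic units. Contig placement votes on a diagonal with k-mer seeds
and verifies full-length identity (accept at ≥ 0.95 identity over ≥ 0.90 of
the contig); genes fully inside the placed interval are "contained",
intersecting ones "partial".

## SNP calling

Pileups count plus-strand bases of ungapped alignments. A call requires
depth ≥ 10 (the published filter) and, as this package's own addition, the
top non-reference base at fraction ≥ 0.2 — a single-alt-allele model meant
to suppress sequencing-error calls; both thresholds are parameters.
Annotation locates the position (PCG > control region > tRNA/rRNA >
intergenic), complements alleles onto the reading strand for minus-strand
genes, and classifies synonymous vs missense by translating the codon pair.
Output is a SNP-table TSV and minimal VCF v4.2.

## Control regions

Tandem repeats are found by seeded self-match: for each unit length (default
3–200 bp) the scan looks for positions where the following block repeats the
unit within a mismatch budget (default 10% per copy), extends greedily over
full copies plus an exact-prefix partial final copy, and resolves
overlapping candidates longest-span-first then smallest-unit-first. Motifs
are fixed regular expressions: polyT `T{5,}`, TATA, `GA{2,}T`, TAA-like
`(TAA){3,}`, ATAA-like `A(TAA?){3,}`, mTERF consensus `ACTAA` — the TA(A)n
stretch classes are published pictorially, and these regexes are this
package's formalization. Stem-loops are exact maximal inverted repeats with
loop length 3–20 and stem ≥ 3 (no thermodynamic folding); nested hits are
suppressed.

## Synthetic data

The generator emulates the study design at desk scale: 75 bp single-end
reads (default 100,000, standing in for a 43-million-read library) drawn
from mature transcripts of the 37-gene layout under the tRNA-punctuation
model — unit body plus a poly(A) tail of 9–40 nt, strand-faithful,
abundances proportional to per-unit weights whose default ranking mirrors
the observed expression ordering (rrnL far highest). The genome is random
sequence with every annotated start/stop codon imposed (internal codons are
random non-stop codons), planted codon contexts for the published SNP sites,
planted CR2 repeat arrays (44 bp × 5 and 169 bp × 2, the observed regimes),
and planted SNPs expressed in reads at a configurable fraction (default 5
variants at fraction 1.0). The base just downstream of each poly(A) junction
is forced non-A so simulated tails are never fully templated. One published
overlap is geometrically unsatisfiable — the *nd6* stop TAA (7387–7389) and
the *cytb* start ATG (7388–7390) demand conflicting bases at 7389 — so
start codons win and the broken *nd6* stop is recorded in the truth object.
The default error rate is 0 (error injection is available); quality-score
realism, GC bias and duplication are not modeled. All randomness flows from
a single integer seed, and identical seeds give byte-identical FASTQ.

Passing end-to-end tests on this simulator demonstrate that the pipeline's
bookkeeping (coordinates, strands, tails, codons, thresholds) is exact; they
do not demonstrate robustness to real-data artifacts (sequencing error,
coverage bias, heteroplasmy, index hopping), which the simulator does not
emulate.

## Problem sizes and determinism

End-to-end tests run one 100,000-read simulation (about 15 s of mapping in
pure Python); property tests use 200 random short codon pairs for the
Nei–Gojobori oracle and the full 64×3 codon-position table for degeneracy.
The pipeline is single-threaded and deterministic: re-running any stage with
the same inputs and seed reproduces identical output bytes.

## Known limitations

- No indel or splice-aware alignment; the internal mapper is exact-match
  with a mismatch bound.
- Divergence site classes are defined on the reference sequence only, and
  the SE is a binomial approximation that ignores between-gene variance.
- Heteroplasmy is modeled only as an alt-allele fraction; no statistical
  genotype model.
- Repeat discovery reports non-overlapping arrays; interleaved or nested
  repeat structures are resolved greedily, not optimally.
- Sequence-dependent integration against the deposited genome accessions
  (overall 21.30% MED vs New World divergence, atp8 Ka/Ks, absolute codon
  counts) requires downloading those accessions and is outside the offline
  test suite.
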