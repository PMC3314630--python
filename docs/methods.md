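# Methods

This note documents the models and procedures implemented in gobiseq, the
parameters that matter, the numerical choices made where the design was
open, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere. GFF3 (1-based
inclusive) is converted at the I/O boundary; BED and bedGraph output are
half-open. FASTA/FASTQ pass through Biopython, SAM through pysam (aligned
reference span = POS + CIGAR reference length; unmapped, secondary and
supplementary records skipped), GFF3 parsing through gffutils, Newick and
tree containers through dendropy. FASTQ qualities default to Phred+33.

## Genome summary statistics

Per replicon: GC% is computed over non-N bases only (N has undefined
composition); coding density is the per-base union of CDS intervals with
overlaps merged across both strands, the only aggregation reproducible
from an annotation alone; mean CDS length excludes pseudogenes, which are
a separate annotation class. Genome totals sum sizes and CDS counts and
weight GC and density by replicon length (two-decimal rounding). Note
that published summary tables do not always use length-weighted
aggregation: for the worked-example table the weighted coding density is
84.44 and the count-weighted mean gene length 856.8, whereas the printed
"All" cells give 85.4 and 863 by an unstated convention. We report the
weighted means and make no claim about those two printed cells.

## Read preprocessing and coverage

Trimming removes the maximal prefix and suffix whose bases all have
quality < 5; interior low-quality bases are untouched, so trimming is
idempotent. The length filter keeps reads strictly longer than 20 bp.
Alignments overlapping an annotated rRNA by at least one base are
excluded — the conservative reading of "mapped into the rRNA regions".
Depth tracks are built by a difference array over aligned spans, pooled
across strands by default (the RNA-seq protocol is not strand-specific),
with per-strand modes available; forward + reverse always equals pooled.
Paired-end mates count as independent alignments — no fragment-level rule
is imposed. Start profiles count biological 5′ ends: the leftmost base of
a forward alignment, the rightmost base of a reverse alignment.

## TSS and ncRNA calling

A TSS is any position whose 5′-end support summed over the control and UV
samples reaches 5 reads ("summed" rather than "each sample ≥ 5": a 3+2
pileup qualifies). Calls are associated with the nearest downstream gene
start on the same strand within a 250 bp window (configurable); the
window is a package choice — the association rule ties a TSS to a gene 5′
end but no published window exists.

ncRNA candidates are maximal runs of transcribed positions (depth ≥ 1)
inside intergenic space — intergenic = complement of the union of
CDS/rRNA/tRNA intervals on both strands — emitted when run length ≥ 30 bp
and mean depth ≥ 15 reads/bp. The mean-depth test applies to the run as a
whole, not per base. Classification consumes externally supplied homology
flags (similarity searches are out of scope): similarity to a known ncRNA
confirms a candidate even when a protein hit coexists; a protein hit
alone rejects it. Both thresholds are inclusive and monotone: lowering
any of min_reads, minlen or mindepth can only add calls.

## Differential expression

Expression is normalised as FPKM = count·10⁹/(CDS length · mapped
reads). The test statistic is a Pearson chi-square (1 df, no continuity
correction) on the 2×2 table of the gene's counts against the rest of
each library — the only contingency constructible from per-gene counts
and library totals. Raw counts are tested (a chi-square needs counts, not
normalised values). The family for Bonferroni correction counts testable
genes only (≥ 1 read over both samples); significance is p < α/m with
α = 0.05. Classification additionally requires a 2-fold FPKM change;
zero counts receive a one-read pseudocount for the fold computation only,
and are flagged. Expected counts below 5 are flagged but not excluded.
No Yates correction is applied. Replicate fold changes, when present, are
averaged; p-values across replicates are not combined (max-p, flagged),
as no principled combination rule is specified for this design.

Calibration: on a 200-replicate null simulation (1000 genes, log-normal
rates, library size 10⁶) the measured family-wise error sits at the
nominal 0.05 within Monte-Carlo error (a long-run estimate over 1000
replicates gives ≈ 0.052). The residual excess is the well-known
anticonservativeness of the asymptotic chi-square in the extreme
Bonferroni tail (per-test level ≈ 5·10⁻⁵) for genes with small expected
counts; it is a property of the specified test, not of the
implementation, and the low-expected-count flag marks the genes affected.
Planted 4-fold genes at mean count 200 are recovered with sensitivity
1.0 and no null miscalls.

Constitutive high expressors are genes holding ≥ 1 % of the mapped
library in both samples.

## Taxonomic affiliation and orthology

Hit filtering is two-pass in the stated order: drop hits with
E-value ≥ 10⁻⁴, then keep hits scoring ≥ 95 % of the best bit score
among the survivors. "Score" is the bit score — comparable across
searches; the raw-score reading is not used. A query with no qualifying
hits is `no_hit`; with unanimous hit phyla it is `assigned`; otherwise
`unresolved`. Queries assigned to Deinococcus-Thermus get an order from
the best-bitscore hit, ties broken by lexicographically smallest subject
id (determinism). Tightening the score fraction degrades monotonically
for assigned queries (a subset of unanimous hits stays unanimous), but an
unresolved query may legitimately become assigned when its discordant
hit drops out.

Ortholog groups are mutual fully transitive reciprocal best hits:
connected components of the cross-genome reciprocal-best-hit graph that
contain at most one gene per genome *and* form a clique; components
failing either condition are rejected and reported. Self-genome pairs are
ignored. Core genes are clusters spanning every genome; a genome's
specific genes are those in no cluster.

## Consensus phylogeny

Bipartitions with bootstrap support ≥ 70 (inclusive — "at least") are
extracted from each gene tree; the two root-child edges of a rooted
binary tree induce the same split and are de-duplicated (larger support
kept); splits without a support value are not extracted. Each recorded
split becomes one column of a taxa × splits 0/1 matrix — duplicates
across gene trees are retained as separate columns, which weights
frequent splits — with taxa absent from the source tree coded missing,
and the side containing the lexicographically smallest defined taxon
coded 0. The distance on this matrix is the normalised Hamming
(p-)distance over mutually defined columns; it is exactly invariant
under column polarity flips, and a taxon pair sharing no defined column
is an error. Hamming is a package choice: the matrix is treated as a
character alignment and no specific distance is prescribed for it.

BioNJ (Gascuel 1997) then builds the tree: pair choice by the NJ
Q criterion Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·); branch lengths by
the standard NJ formulas; reduction
d(u,k) = λ(d(i,k)−b_i) + (1−λ)(d(j,k)−b_j) with variances initialised to
the distances, v(u,k) = λv(i,k) + (1−λ)v(j,k) − λ(1−λ)v(i,j), and
λ = 1/2 + Σ_k(v(j,k)−v(i,k)) / (2(r−2)v(i,j)) clamped to [0, 1] (1/2
when v(i,j) = 0). Q ties break on the lexicographically smallest taxon
pair, so results are order-independent. Negative branch lengths are
reported as computed, with an optional clamp-to-zero flag. The output is
unrooted (trifurcation at the root), binary, with n−3 internal edges.

Why the unanimous case is exact: when all gene trees carry the same
fully supported topology, the p-distance is the split metric of that
tree — an additive metric with unit internal and zero pendant edge
lengths (up to the column normalisation) — and neighbor joining is
consistent on additive metrics, so the common topology is returned.

## Synthetic data

Every generator is a pure function of `SimConfig` (one numpy Generator
seeded once; sub-generators draw in documented order), and emitted files
round-trip through the package's own readers. Default scale is a
desk-sized genome — two replicons (60 kb + 25 kb), 60 CDS of 300–1500 nt
with 60–400 bp gaps, GC 0.69, two rRNA and four tRNA features — chosen
to exercise every code path in seconds while mirroring the layout of a
multi-replicon bacterial genome.

Counts: per-gene rates are log-normal(μ=1, σ=1) (heavy-tailed, like real
RNA-seq); a gene's expected count is library size × genic fraction (0.9)
× its rate·length share, and UV expectations are multiplied by the
planted fold (default: 5 % induced at fold 4, 5 % repressed at 1/4).
Counts are Poisson draws; library totals are the configured mapped-read
totals, so the expected FPKM ratio of a planted gene equals its fold
exactly. The generator does not model overdispersion between biological
replicates, positional bias, or multi-mapping — so passing tests
demonstrate correctness of the procedure, not robustness to real-library
noise.

Coverage is simulated directly rather than via read alignment (an
optional SAM emitter produces perfectly aligned reads for exercising the
SAM path): genic depth is spread uniformly per gene; TSS pileups of 5–50
reads are planted at the 5′ starts of a random gene subset and split
binomially between samples; intergenic transcripts (30–200 bp at 15–60×)
are planted at most one per gap with a 1 bp zero margin, so in noise-free
mode the planted intervals are exactly the maximal runs and recovery is
provably exact. Background noise, when enabled, adds independent
singleton positions.

Hit tables plant one label per query (default mix 60 % assigned, 25 %
unresolved, 15 % no-hit): assigned queries get unanimous qualifying hits
plus decoys that fail exactly one filter (score below the 95 % band, or
E-value above the cutoff); unresolved queries get two discordant in-band
hits; no-hit queries get nothing or only above-cutoff hits. Recovery is
therefore 100 % by construction — these fixtures validate the filter
logic, not BLAST itself.

Gene trees: a random binary species tree (branch lengths U(0.1, 1));
each gene tree applies a nearest-neighbor interchange per internal edge
with probability `split_noise`, then supports are assigned by split
status — true splits U(70, 100), perturbed splits U(30, 69), both
configurable. With the defaults, perturbed splits fall below the 70 %
threshold, which is what makes the consensus robust to moderate noise.

## Problem sizes and determinism

The test suite and the acceptance script use the generator defaults plus
the stated simulation designs (200 null replicates of 1000 genes for
FWER; 50 planted fold-4 genes at mean count 200; 1000 random additive
matrices with n ≤ 12 for BioNJ; 500 planted affiliation queries; 500
polarity flips for the p-distance property). All randomness is seeded;
reruns are byte-identical, including full pipeline output directories.

## Known limitations

- The chi-square DE test has no dispersion model; it is the specified
  procedure, not a recommendation over modern count models.
- TSS–gene association uses a fixed window and annotated starts only;
  operon-internal and antisense starts are reported unassociated.
- The ncRNA caller assumes pooled, non-strand-specific coverage and
  cannot separate overlapping antisense transcripts.
- p-distance treats every recorded split occurrence as an independent
  character; no correction for non-independence between splits of the
  same gene tree is attempted.
- BioNJ may produce negative branch lengths on non-additive input; they
  are reported faithfully unless clamping is requested.
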