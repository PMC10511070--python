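# Methods

This note records the models, conventions and design choices behind
`alignstat`, in the spirit of a statistical-software methods appendix.
Nothing here states a number the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and coordinates

The central object is an `Alignment`: ≥2 equal-length, uppercased DNA
sequences with unique ids, `-` the only gap character.  `N` and the
IUPAC ambiguity codes are accepted on input but treated as *missing*
everywhere downstream; `*` and `.` are rejected rather than coerced,
since silently reinterpreting them hides upstream format problems.
Duplicate FASTA ids are an error for the same reason: every matrix in
the pipeline is keyed by id, and suffixing duplicates would quietly
shuffle samples.

All coordinates are 1-based inclusive, matching GFF3 and VCF.  Variant
positions live in *reference space*: a chosen aligned sequence (or the
majority consensus) is scanned left to right and its non-gap columns
receive successive positions; columns where the reference is gapped
have no position and are skipped (with a warning and a count) when
writing VCF/HAPMAP or joining annotations.

## Alignment statistics

GC content is (G+C)/(A+C+G+T) per sequence; gaps, N and ambiguity codes
are excluded from numerator and denominator, which makes the value
identical on gapped and ungapped forms of the same sequence and stable
under masking.  Column entropy is Shannon entropy in bits over the
called A/C/G/T frequencies renormalized to exclude gaps and missing
residues — gap information is deliberately carried in a separate
`gap_fraction` rather than folded into the entropy, so the two signals
(substitution diversity vs. indel coverage) stay readable
independently.

Pairwise dissimilarity is 1 − identity.  The default `pairwise_delete`
mode drops, per pair, every column where either member is gapped or
missing; this treats indels as missing data for similarity, consistent
with reporting them separately as indel blocks.  `gap_as_state` treats
`-` as a fifth character state for users who want indels to count as
differences.  A pair with zero comparable columns is assigned
dissimilarity 1 with a warning — the least-commital value that keeps
the matrix in [0, 1].

The consensus takes, per column, the most frequent called base if its
frequency among non-gap residues reaches `min_freq` (else `N`); a gap
is emitted only where gaps are a strict majority.  Ties break
alphabetically (A<C<G<T) so the consensus is a pure function of the
alignment.

## Variant model

Any column containing a gap is an *indel site* and excluded from SNP
analysis.  This keeps the SNP and indel analyses disjoint and
guarantees a single-base REF in the VCF; the cost is that SNPs
overlapping an indel in even one sequence are not called.  Among
gap-free columns, the count of distinct called bases gives invariant /
biallelic / multiallelic.  The major allele is the most frequent called
base (ties alphabetical), the minor the second; minor-allele frequency
is computed over called alleles only.  Biallelic filtering keeps sites
with missing fraction ≤ `max_missing` (default 0.2) and minor allele
count ≥ `min_mac` (default 1); both are exposed as flags since no
canonical thresholds exist for gene-scale MSAs.  Genotypes are haploid:
0 = major ("wild" form), 1 = minor, NA otherwise.

VCF output is VCFv4.2 with CHROM set to the reference sequence id —
the tool operates at the gene level, so the "chromosome" is the gene —
and haploid GT values 0/1/`.`.  HAPMAP output uses the 11-column
single-letter haploid dialect (inbred-line style): MSA rows are haploid
observations, so diploid genotype pairs would be fiction.  Unknown
metadata columns are `NA`.

Indel blocks are maximal runs of `-` per sequence; blocks with an
identical (start, end) span across sequences get a sharing count, which
is what makes shared deletions visible as a group feature.

## Trees, orderings, PCA, SNP clustering

Neighbor joining follows the Saitou–Nei Q-criterion with the standard
branch-length formulas.  Determinism is pinned down explicitly: ties in
Q break on the smallest (i, j) pair in current label order, negative
branch-length estimates are clamped to zero with a warning, and the
final three lineages form the trifurcating root of the unrooted tree.
On additive matrices the algorithm is exact (path lengths reproduce the
input to numerical precision), which the tests exploit: 50 random 5–10
taxon trees with branches in [0.1, 1] are regenerated from their
path-length matrices with all splits recovered, and the implementation
is cross-checked against an independent NJ implementation.  Leaf order
for display visits children by ascending subtree-minimum label, so the
order is a function of the unordered tree, not of construction history.

Heatmap ordering offers the tree leaf order and an agglomerative
ordering of 1 − Pearson correlation of matrix rows (average or complete
linkage); constant rows get zero correlation with a warning.

PCA is covariance PCA (centered, unscaled — the 0/1 coding is already
bounded) on the genotype matrix after per-site mean imputation of
missing calls, which preserves site means and is the standard choice
for genotype data.  Sites that are entirely missing are dropped with a
warning.  Component signs are fixed by making each loading vector's
largest-magnitude entry positive, so results are reproducible across
runs and platforms.  The two modes differ only in orientation: samples
as observations (genetic relationships among sequences) or SNPs as
observations (relationships among sites).

SNP-group clustering is k-means (10 restarts, fixed seed) on the first
`n_components` (default min(5, available)) SNP-mode score columns, for
k in 2..10, selecting k by maximum mean silhouette (ties to the smaller
k).  K-means on PCA scores was chosen because the groups of interest
are by construction directions of co-variation in genotype space, and
silhouette gives a parameter-free k selection; labels are renumbered
1..k by descending cluster size for stable reporting.  Given the seed,
the whole path is bit-reproducible.

## Annotation joining

GFF3 features are matched to variant reference positions by
containment; when features overlap (a SNP inside an exon inside its
gene), the smallest span wins as the most specific context, then file
order.  Strand is recorded but ignored for containment — features are
used as positional context only, not for effect prediction.

## The synthetic generator

`simgen.simulate_alignment` emulates the input the pipeline is built
for: closely related gene sequences with (i) blocks of biallelic SNPs
sharing a latent carrier partition, (ii) shared deletions, (iii)
uniform missingness.  One seeded NumPy generator drives all draws in a
documented order, so fixtures are byte-stable.  Carrier sets are drawn
with size in [n/4, (n−1)/2], so the ancestral base always remains the
major allele and the planted minor allele is exactly the recovered
minor allele.  Each SNP in a block copies the block partition with
probability `block_corr`, else draws an independent partition.  The
truth record labels *realized* correlated groups: sites sharing a
carrier partition share a group id (blocks take 1..n_blocks; an
independent draw founds its own group).  An independently drawn SNP
shares no correlated variation with its block, so no clustering method
could recover a block label for it; scoring against realized groups
measures what the method can in principle get right.

Defaults — 30 sequences, 800 columns, 2 blocks × 10 SNPs, full block
correlation, no indels, no missingness — describe a small gene panel
with clean two-haplotype structure: large enough that PCA and k-means
operate away from degenerate edge cases, small enough that every test
runs in milliseconds.  What the generator does *not* emulate: phylogenetic
autocorrelation of substitutions, realistic indel length distributions,
sequencing-error base miscalls, or rate variation along the gene.
Passing recovery tests therefore demonstrates correctness of the
extraction and clustering machinery on its stated model, not robustness
to every property of real population data.

## Numerical and degenerate-input conventions

* Dissimilarities, explained-variance fractions and silhouette values
  are compared in tests at 1e-8–1e-9 absolute tolerance; NJ additivity
  at 1e-9; Newick branch lengths are written at 12 significant digits
  so round trips preserve path lengths to below 1e-9.
* PCA on zero-variance data raises rather than returning NaN fractions.
* Fewer than 3 taxa (NJ) or fewer than 3 sites (clustering) are errors,
  not silent degenerate outputs.
* Circular layouts refuse more than 300 sequences and advise the linear
  view; each column gets an equal slice of (360 − reserved_gap)
  degrees, and arcs are the run-length encoding of per-column
  match/mismatch/gap against the majority consensus — a parameter-free
  baseline for "shared regions".
* SVG rendering pins matplotlib's hash salt and strips the date
  metadata so that pipeline outputs are byte-identical across runs.

## Problem sizes in the checks

The acceptance script simulates at the generator defaults (20 planted
SNPs over 30×800 alignments), averages the clustering ARI over 100
seeds, uses 50 random trees and 50 random fixtures for the NJ and
oracle checks, and one 15×400 simulation for the VCF round trip —
sizes chosen to exercise every code path while keeping the whole script
in the tens of seconds on one core.

## Known limitations

Indels are reported as blocks, never genotyped into the VCF;
multiallelic sites are classified but not exported; no bootstrap
support, no maximum-likelihood trees; no formal LD statistics (r², D′)
— the SNP grouping is a clustering view, not an LD estimator; protein
sequences are parsed but none of the statistics are amino-acid aware.
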