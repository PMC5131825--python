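# Methods

This note documents the models and procedures implemented in `zfdiv`, the
parameter defaults and the reasoning behind the open design choices, and
what the synthetic data can and cannot show.

## Peak processing and binding-site similarity

**Replicate merging.** Peak summits from biological replicates are clustered
per chromosome by single linkage with a 50 bp threshold: adjacent summits at
most 50 bp apart chain into one cluster, so a chain can span more than 50 bp
end to end — this is the transitive reading of "summits within 50 bp of each
other", and it is documented here precisely because the alternative
(bounded-diameter clustering) gives different merges on dense summit runs.
Each cluster becomes one peak with score = sum of constituent scores and
summit = score-weighted mean of constituent summit coordinates, rounded to
the nearest integer with exact halves rounded toward the lower coordinate.
The merged interval is re-centered on the summit using the widest
constituent width. Merging is idempotent.

**Composite background.** Experiment-specific backgrounds are modeled as a
non-negative mixture of candidate input tracks on a fixed-width bin grid
(default 1 kb). Weights solve min‖Aw − y‖₂ s.t. w ≥ 0 by Lawson–Hanson
active-set NNLS (`scipy.optimize.nnls`); tracks are library-size normalized
to the target before fitting, and the fitted combination is rescaled to the
target's total count. Whether counts or densities enter the fit is exposed
via the `normalize` flag because the convention is genuinely ambiguous.

**Similarity.** Binding-site similarity is base-pair Jaccard in the
bedtools sense: both sets are internally merged, then |intersection bp| /
|union bp| over all chromosomes; empty vs empty is defined as 0. The
protein × protein matrix takes the maximum Jaccard over all replicate-pair
combinations, which favours reproducible overlap over averaged noise. An
experiment is "replicate-specific" when, ranking all other experiments by
Jaccard, the top-ranked one is a replicate of the same protein; a tie at
zero similarity does not count as specific.

## Motif analysis

PWMs carry per-position probabilities over ACGT, a background distribution
and a pseudocount ε = 0.01; scores are log₂ odds with ε added to numerator
and denominator. Positions containing N score −∞. The reverse strand is
scanned with the reverse-complement matrix so hit coordinates stay on the
forward strand; ties break to the leftmost position, forward strand first.
Log base 2 and the ε value are conventions, not claims; both are exposed.

**Dinucleotide shuffle.** The null for motif evaluation is the exact
Altschul–Erickson shuffle: an Eulerian path over the dinucleotide transition
multigraph, with the last edge out of each vertex chosen so the chosen edges
form a tree into the terminal vertex. This preserves the dinucleotide count
vector and the first/last base exactly; runs of non-ACGT characters are held
fixed and the intervening segments shuffled independently.

**AUROC.** For the top 500 peaks by score, the ±250 bp sequence around each
summit is scored and paired with a single shuffle of itself. The AUROC of
best-score-per-sequence for real vs shuffled is computed from the
Mann–Whitney rank statistic with ties counting ½. One shuffle per positive
(a paired design) keeps the negative set composition-matched per sequence;
best-score-per-sequence (rather than pooled per-position scores) matches
the question "does the motif distinguish peaks?".

**Window and cutoff.** The central-enrichment window scans candidate
half-widths w ∈ {10, 20, …, flank} and keeps the w with the smallest
one-sided binomial p-value for the count of best-hit centers within ±w of
the summit; the uniform null is w/(flank − L/2), because a width-L motif's
center cannot reach the last L/2 bases of the window. If no w reaches
p < 0.01 the full flank is returned flagged non-significant. The affinity
cutoff is chosen on a grid of observed best-score quantiles to maximize
(fraction of the top 20% of peaks by score with a hit ≥ cutoff) / (same
fraction among the rest), subject to ≥5% of peaks retaining a hit; ties go
to the higher cutoff. The 20% top fraction is a default, not a doctrine;
it is a parameter.

## Genomic context

Feature fold enrichment histograms signed summit-to-nearest-feature
distances and divides bin-wise by the same histogram for uniformly drawn
random points with matched per-chromosome counts; bins with zero random
mass are NaN, never infinite. Histone fold change is log₁₀ of the mean
signal in ±1 kb windows around summits over the genome-wide mean of the
track (uncovered bases count as zero signal).

ERE enrichment uses a one-sided binomial test with null probability equal
to the class's genomic coverage after dilating each instance by half the
median peak width per side (approximating "a random peak overlaps the
class"); for classes covering more than 20% of the genome the binomial
approximation degrades and a within-chromosome permutation test (positions
re-drawn uniformly, lengths preserved, default 1000 permutations) is used
instead. BH correction across classes at FDR 0.01.

SNP depletion compares SNP counts in the union of a protein's motif-hit
intervals against the union of ±20 bp flanks minus the motif territory —
unioned territories prevent double counting where hits or flanks overlap;
the per-hit alternative would over-weight clustered hits. The one-sided
(depletion) binomial p-value is BH-corrected across proteins at FDR 0.025,
and a pooled test aggregates counts over all proteins. Zero observable SNPs
yields p = 1 with a warning rather than an error.

## AP-MS scoring

The low-variation filter drops preys whose coefficient of variation of
summed counts across baits is below 0.5 — ubiquitous contaminants are
abundant *and* flat. Interaction calls come from externally supplied
confidence scores (cutoff 1.0) when present; otherwise a documented
fallback calls a pair when its summed count is ≥5 and ≥2× the expectation
under proportional allocation.

Odds ratios: for prey j, the background probability p_j is estimated from
baits whose pair with j is not called significant, p_j = (Σ c + α)/(Σ T +
αP) with α = 1 and P preys; the bait-specific probability is q_ij =
(c_ij+α)/(T_i+αP), and OR_ij = [q_ij/(1−q_ij)]/[p_j/(1−p_j)]. The algebra
is a reconstruction of the background-probability idea; α and the formula
are exposed in the API. A prey significant in every bait falls back to the
negative-control baits; with none, it is an error rather than a silent
guess. At the α → 0 limit, a bait's ORs for its significant preys are
exactly invariant to rescaling that bait's counts.

Regulatory direction: a bait is activator-only / repressor-only / both /
none by the union of curated directions over its significant preys ("both"
preys count on both sides). The expression-response test compares
induced-minus-control changes of bound-promoter genes (±10 kb of TSS)
against all other genes with a two-sided Wilcoxon rank-sum test, BH across
baits at FDR 0.01, direction = sign of the median difference.

## Diversity estimation

PAM is the classic BUILD (greedy cost-minimizing medoid additions) plus
SWAP (steepest-descent single swaps to convergence), deterministic with
lowest-index tie-breaks. On cluster-structured data with matching k the
result attains the exhaustive-enumeration optimum; on unstructured data
single-swap local optima exist — the reference R implementation
(`cluster::pam`) lands on the same ones, which is the expected behaviour of
the algorithm, not an implementation artifact. Silhouettes follow the
standard (b−a)/max(a,b) with singleton clusters scored 0 (Rousseeuw's
convention); a tie-degenerate assignment (all points on one medoid) scores
0. The profile count is the *largest* k whose mean silhouette is ≥95% of
the maximum over k ∈ {2, …, k_max} (default k_max = min(n−1, 100)) — an
estimate of how many distinct functional profiles the data support, not of
the "true" cluster number. All-zero distance matrices are flagged
degenerate. Average-linkage hierarchical clustering is provided as the
robustness alternative.

Motif distance is 1 − the best mean per-column Pearson correlation over all
relative offsets with ≥4 overlapping columns and both orientations;
constant columns compare as 1 when equal, else 0. This is a documented
substitute for an unspecified motif-similarity measure. Peak distance is
1 − Jaccard; PPI distance 1 − Pearson on log-transformed odds-ratio
vectors; expression distance 1 − Pearson on differential-expression
vectors; sequence distance 1 − fractional identity from Biopython global
alignment. Cross-parameter correlation vectorizes the upper triangles of
the similarity matrices (optionally restricted to a pair subset such as
paralog pairs) and reports pairwise Pearson correlations with listwise NaN
dropping per parameter pair.

## Neutral codon evolution

Each base of each domain accrues a Poisson(r·t) number of substitution
events applied sequentially, each replacing the base with one of the other
three uniformly; this reproduces 1 − e^(−rt) for the per-site hit
probability and ¾(1 − e^(−4rt/3)) for a net base change. Defaults: r =
2.2 × 10⁻⁹/site/yr, t = 2 × 10⁷ yr, 23 codons per domain (the canonical
C2H2-ZF repeat span; the length is exposed and a sensitivity sweep over
21–28 codons is provided because stop accrual, unlike per-codon amino-acid
turnover, scales with length), 10⁵ domains, start sequences uniform over
the 61 sense codons. A codon counts as changed when its translation
differs (stops count as changed); a domain counts toward stop accrual when
any codon became a stop. No transition/transversion bias, no selection, no
indels — this is deliberately the back-of-envelope neutral model; the
substitution-model field is the extension point.

## The synthetic world

The generator emulates the statistical structure the analyses assume, at
desk scale: a 4 × 5 Mb uniform-composition genome (first-order Markov with
configurable dinucleotide bias — sufficient for the dinucleotide-shuffle
null; real genomes have higher-order structure, isochores and repeats that
this deliberately lacks), 12 proteins in 3 clusters of binding sites placed
on a non-overlapping slot grid. Sharing a fraction f of identical
fixed-width sites gives base-pair Jaccard f/(2−f), so pool sizes are set by
the inverse map f = 2J/(1+J) to hit within-cluster J = 0.5 and
between-cluster J = 0.02 in expectation. Replicates are jittered copies of
the truth set (summit noise ~ round(Normal(0, 10 bp)), dropout 0.1 — the
replicate noise model is a choice, not a measurement). A 16-column
concentrated PWM per protein is written into the genome at 90% of peak
summits; proteins sharing a site plant in distinct lanes (offsets 0, ±L,
±2L … from the summit) so co-bound sites carry every owner's motif. SNPs
are Bernoulli(0.01/bp), thinned to keep-probability 0.3 inside motif hits.
AP-MS counts are Poisson with planted module means of 25 modulated by
per-pair log-normal strengths (σ = 0.6, so each bait has a distinctive
profile, as real baits do), abundant flat contaminants (mean 10) and a 0.2
baseline; negative-control baits receive only contaminants and baseline.
Expression is log-scale Normal noise (σ = 0.5) around a per-gene baseline,
with bound-promoter genes shifted by +1.0 in the corresponding induced
sample. All synthetic SNPs are treated as common SNPs; commonness is not
modeled.

What passing tests on this world show: that the statistics recover planted
structure of realistic magnitude under Poisson/Gaussian noise, that the
pipelines are deterministic given a seed, and that the estimators are
calibrated under their own nulls. What they do not show: performance on
real chromatin (mappability artifacts, copy-number, peak-width
heterogeneity, correlated replicates, batch effects in AP-MS, non-log-normal
expression dispersion).

## Numerical and interface choices

Coordinates are 0-based half-open throughout; BED column 5 carries the
score and column 7 the summit offset from start (MACS convention); motif
exchanges use MEME minimal format; matrices travel as TSV with header
labels. One global seed is split into named substreams per stage, so stage
outputs are independent of each other's draw counts. A generic
minimum-peak-count QC filter (default 500) is provided; score-based QC
filtering beyond that would require a score definition this package does
not compute. The pipeline writes a manifest (parameters, seed, package
versions, output checksums) so a run is reproducible byte for byte.

## Known limitations

Dataset-level summaries of the real study (median motif AUROC, the
fraction of protein pairs above a Jaccard threshold, replicate-specificity
counts, the TRIM28/H3K9me3 correlation) depend on the deposited data and
are out of scope here; the test suite exercises the same machinery on
synthetic data instead. SAINTexpress-style interaction confidence scoring
is consumed as an optional input, never computed. Paralog grouping,
motif discovery and read-level processing are out of scope.
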