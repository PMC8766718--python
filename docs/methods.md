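# Methods

## Scope and pipeline

`hicdyn` implements a desk-scale Hi-C condition-comparison analysis:
aligned read-pair QC, binned contact matrices with an expected-count
model, cumulative-binomial interaction calling at fine resolution,
anchor-overlap comparison of interaction sets across conditions,
fold-change classification of interacting-gene expression, per-anchor
epigenetic-state statistics with a permutation null, GWAS-SNP density
comparison, and FASTA export of motif-analysis windows.  Alignment,
FPKM quantification, motif discovery and visualization are out of
scope: pairs, FPKM tables and SNP lists are consumed as inputs, and the
pipeline emits Circos-ready BEDPE and matrix TSVs instead of plots.

## Read-pair QC

Pairs are removed in a fixed precedence so the report is an exact
partition of the input: PCR duplicates (identical coordinates and
strands; on by default, switchable) → same-fragment pairs
(self-ligation/dangling ends) → adjacent-fragment pairs (re-ligation)
→ same-chromosome inward-facing pairs closer than the insert window
(un-digested genomic fragments) → pairs in which *neither* read has a
restriction site within the insert window downstream of its 3′ end.
The insert window defaults to 500 bp, the typical Hi-C size-selection
scale; the window and the duplicate switch are parameters because the
field does not agree on exact values.  A position lying on a
restriction site belongs to the downstream fragment (half-open
convention, used consistently everywhere).

## Expected-count model

Contacts are binned genome-wide (200 kb for matrices, 1 kb for
calling).  Bins whose observed marginal is below 20% of the median
positive marginal are masked from all statistics — a low-coverage guard
needed because fine bins without a restriction site receive almost no
reads.

The distance-decay curve `f` is the mean observed count per cis bin
pair at each bin separation, pooled over chromosomes.  At fine
resolution the sparse tail is stabilized by log-spaced distance strata
merged until each holds ≥ 50 observed reads.  `f` is smoothed to be
non-increasing by weighted isotonic regression **for separations ≥ 1
bin**; the diagonal (within-bin separations) is its own stratum outside
the monotone constraint, because sub-bin separations are governed by
fragment geometry and insert-size selection rather than the polymer
decay law, and coupling the diagonal into the isotonic fit distorts the
first off-diagonal stratum.

Inferred bin totals n\* start at the observed marginals and follow a
damped multiplicative update n\*_i ← n\*_i · √(observed marginal_i /
model marginal_i).  The square-root damping is deliberate: n\* enters
the expected counts bilinearly, so the undamped multiplicative step
overshoots by exactly a factor of two in log space and 2-cycles on
symmetric data; the damped step descends monotonically and converges in
one step in the pure-quadratic case.  Model marginals are computed per
chromosome as a Toeplitz matrix–vector product (FFT-based), so the fit
is O(B log B) per iteration and runs comfortably at 1 kb bins.
Convergence: max relative change of any n\* below 1e-4 or 200
iterations; an objective (squared marginal residual) that rises for 5
consecutive iterations raises a diagnostic error.  N\* is fixed at the
total retained read count.  The trans distance term is recalibrated
each iteration so the expected trans mass equals the observed trans
mass.  After convergence the expected mass over unmasked pairs matches
the observed mass to well within 0.5%.

The hill-climbing scheme is a stand-in validated by parameter recovery
(bias correlation ≥ 0.9, decay-slope error < 0.15 on a million-pair
simulation), not a claim of bit-compatibility with any external
implementation.

The normalized matrix is observed/expected (0/0 → 1; positive observed
over zero expected is masked with a warning).  The correlation matrix
is the Pearson r between rows of log2(obs/exp), computed over the
columns finite in both rows and excluding the pair's own two columns —
the standard compartment-analysis practice; constant or empty profiles
mask the bin.

## Interaction calling

Every unordered unmasked locus pair at ≥ 2 resolution units of cis
separation (adjacent-tile artifacts excluded), plus every trans pair,
is a candidate.  A candidate with observed k is scored with the
upper-tail cumulative binomial P(X ≥ k), X ~ Binomial(N\*, e_ij/N\*),
evaluated through the regularized incomplete beta, and reported when
p ≤ α (default 0.05, uncorrected — the conventional threshold for this
analysis; a Benjamini–Hochberg switch exists but is off by default) and
k ≥ 5 (`min_observed`).  The candidate count is carried on the result
so empirical type-I rates can be measured.  Anchors are half-open
resolution-sized tiles; cis/trans classification, median cis anchor
separation and a log-strata distance profile are derived statistics.

## Condition comparison

Two interactions match when their anchors overlap pairwise (≥ 1 bp,
same chromosome) in either orientation; a stricter reciprocal-fraction
mode is available.  For a chosen reference condition the package
reports pairwise-shared, k-way-common and exclusive counts; because
match multiplicity makes these counts reference-dependent, the CLI
prints them for every choice of reference rather than picking one.
Expression is classified by log2((FPKM_t + 1)/(FPKM_c + 1)) with a
2-fold threshold (both parameters exposed; the pseudocount guards
zero FPKM).  Group comparisons use the two-sided Mann–Whitney U test
with seeded equal-size sampling of non-interacting control genes.  At
coarse resolution, interactions collapse onto 200 kb blocks (tiles
touched by ≥ 1 anchor); per-block cumulative member-gene FPKM is
compared between common and condition-unique blocks the same way.

## Annotation statistics

Anchor state assignment: the state with maximal base-pair overlap, ties
toward the lower label; overlapping state maps are supported and the
full overlap set is also returned.  Same-state preference compares the
observed fraction of interactions whose anchors share a primary state
against K randomized control draws (default 1000) that preserve record
count, anchor lengths, cis/trans split and the observed cis-distance
distribution; the permutation p-value is (1 + #{null ≥ obs})/(K + 1),
floored at 1/(K+1), alongside a normal-approximation p for very small
tail probabilities.  For controls placed at distances far above the
segment length the null same-state probability approaches Σ_s w_s² over
base-pair shares — a closed form the tests check.

GWAS analysis: the interacting genome is the merged union of anchors;
the control is a seeded random interval set with the same total length
and piece-length distribution drawn entirely from the complement (≥ 1
bp of overlap with the union disqualifies a placement); the background
is all unique SNPs over the genome length.  The depletion ratio is
control frequency / interacting frequency.

Motif-region export emits, for every interaction with ≥ 1 anchor
overlapping a protein-coding gene body, the 1 kb (configurable) window
centred on each qualifying anchor midpoint, clipped to chromosome
bounds and deduplicated by coordinates.

## Synthetic data generator

No generative model is published for this kind of study; every
distributional choice below is an explicit stand-in, validated by the
recovery tests.

* **Genome**: 3 chromosomes × 2 Mb, restriction sites with exponential
  spacing, mean 4 kb (the HindIII scale in *A. thaliana*).
* **Contacts**: an informative pair falls in bin pair (i, j) with
  probability ∝ bias_i · bias_j · kernel(d); cis kernel
  max(d, 1 kb)^(−α) with α = 1 (matching the qualitative decay of real
  data), trans kernel constant at 5% of the 100 kb cis level.  Biases
  are lognormal (σ = 0.3).  Contacts are modelled **between distinct
  bins**: within-bin (sub-resolution) ligation structure is not
  simulated, because such pairs cannot be placed on non-adjacent
  fragments in bins with few restriction sites and would contaminate
  the QC truth labels.  Planted pairs multiply their bin pair's weight
  by an enrichment fold (> 1); when a fragment map is supplied they are
  restricted to site-bearing bins, since siteless bins cannot receive
  reads.
* **Read geometry**: each mate sits 1–400 bp from a restriction site on
  the strand facing it — real Hi-C junction geometry — so informative
  pairs pass the 3′-end site rule; cis mates are re-placed until they
  occupy non-adjacent fragments at ≥ 1 kb separation.  Contaminants are
  same-fragment and adjacent-fragment pairs in equal expected shares;
  every record carries a hidden truth label.
* **Tracks and tables**: epigenetic states are exponential-length
  segments tiling each chromosome with weighted labels; SNPs are
  uniform with rejection-thinned density inside depleted regions; FPKM
  is lognormal (log2 base ~ N(3.3, 2), per-condition log2 noise
  σ = 0.25) with effect genes shifted by their true log2 fold-change.

What the generator does **not** emulate: mappability structure, the
pericentromere/telomere geometry of a real karyotype, domain/compartment
organization, replicate structure, or read sequences.  Passing recovery
tests therefore demonstrate the correctness of the estimators under the
stated model, not their behaviour on every artefact of real libraries.

## Problem sizes in the tests and acceptance script

Recovery experiments use the scales at which their statistics are
well-powered on one CPU: 10⁶ pairs at 10 kb bins for bias/decay
recovery; 2×10⁶ null pairs at 1 kb for the type-I rate (≥ 10⁴ tested
pairs); 4×10⁶ pairs for planted-pair power — chosen by an a-priori
calculation so each planted pair at 10× fold and 10–40 kb separation
expects ≫ 5 reads; 2×10⁴ SNPs for the depletion ratio; 200–1000
permutation replicates for the same-state null.

## Known limitations

* The expected model is marginal-matching, not a full likelihood; at
  1 kb, per-bin fragment geometry leaves mild per-bin miscalibration
  that makes the binomial p-values slightly anti-conservative in dense
  data (the measured type-I rate remains an order of magnitude below
  α).
* Counts reported for set overlaps are reference-record counts, which
  is why they are printed for every reference.
* The permutation p-value cannot fall below 1/(K+1); the
  normal-approximation p is reported for smaller tails.
* BAM/SAM input is out of scope; convert with
  `samtools view -F 0xF00 ... | awk` -style one-liners or any pairs
  extractor producing the 7-column format.
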