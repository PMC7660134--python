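# Methods

`protloc` re-implements, as a tested library, the quantitative analysis
chain used to study mRNA localization to cell protrusions: compartment
enrichment statistics on fractionated transcriptomes/proteomes, iCLIP
crosslink and density-cluster analysis, pulsed-SILAC translation
accounting, and RNA-FISH localization metrics. This note records the
models, the parameter choices, and the places where the design was
genuinely open.

## Statistical kernel (`protloc.stats`)

**Category rank test.** Category-level shifts are scored with a
Wilcoxon–Mann–Whitney test of the category members against their
complement on a per-feature score vector (a log2 ratio or a cross-sample
mean). We report the rank-biserial enrichment score

    s = 2·U / (n1·n2) − 1,  s ∈ (−1, 1),

where `U` counts member-over-complement wins with ties counted half. `s`
is +1 when every member outranks every non-member, 0 under exchangeability,
and its sign gives the direction of the shift. The test itself names no
score, so a bounded, sign-interpretable standard one was chosen.

**Exact versus approximate p-values.** When `n1·n2 ≤ 200` the two-sided
p-value comes from the exact permutation null of the member rank-sum,
computed by dynamic programming over doubled midranks (ties are therefore
handled exactly; this equals full enumeration over all C(n, n1) member
assignments, which is the independent oracle in the test suite). Above the
switch point we use the normal approximation with continuity correction
and the standard tie correction of the variance; the suite checks
|Δp| ≤ 0.01 against the exact null at n1 = 10, n2 = 40. Fully tied inputs
are degenerate: s = 0, p = 1.

**Multiple testing.** Benjamini–Hochberg step-up, implemented directly
(order-preserving, clipped to [0, 1]) and cross-checked in tests against a
literal hand step-up and against statsmodels. The correction family is one
enrichment call (across categories) or one meta-analysis call (across
features); output tables carry the family implicitly in their shape. The
published analyses quote a single corrected p per category without naming
the family, so correcting across all categories tested in the same call is
a recorded interpretation.

**Meta-analysis.** Cross-line enrichment uses a per-feature two-sided
one-sample t against 0 (≥ 3 non-missing values required; zero-variance
rows are flagged degenerate with p = 0 if the mean is nonzero, p = 1
otherwise), BH across features, default FDR 0.05 for the volcano flags.
Over-representation of categories in a target gene set uses the one-sided
hypergeometric upper tail, BH across categories, default FDR 0.02.

**2D enrichment.** Each category is scored independently in two contrasts
(e.g. knockdown response in protrusions and in cell bodies); a category is
significant when either dimension passes BH at the FDR (joint q =
min(q_x, q_y)). The quadrant of the two score signs separates concordant
categories ("expression change") from discordant ones ("mislocalization
candidate").

## Compartment enrichment (`protloc.compartment`)

Counts are scaled to counts per million per column before the ratio (the
two fractions are separate libraries of very different depth), a
pseudocount (default 1 CPM) avoids infinities for dropout genes while
barely perturbing well-measured ones, and genes with summed raw counts
below `min_count` (default 10; 3'-end counting is sparse) are dropped per
sample and reported. Ratios are log2(P/B) with optional per-sample median
subtraction (the default), which removes the global compartment offset
without changing any between-gene differences. Knockdown contrasts are
oriented NT/KD so that a positive value means loss upon knockdown.

## Pulsed SILAC (`protloc.silac`)

Whole-cell H/M ratios measure translation-rate changes between open-pore
(protrusion-forming) and closed-pore conditions. The two biological
replicates are reciprocally labeled; a per-replicate `label_scheme` column
("H_open"/"M_open") harmonizes orientation, after which outputs are
invariant to permuting (M, H) together with the scheme. Zero intensities
propagate to missing, never to ±inf; proteins quantified in only one
replicate go to a side table rather than the scatter matrix.

Compartment accounting divides each label's iBAQ intensity by its total
over compartments, independently per label, so old (L) and nascent (M, H)
pools each distribute to 100%. The old-versus-nascent comparison is a
two-tailed homoscedastic two-sample t-test on nuclear (and cytosolic)
percentages — the published "two-way t test" wording is interpreted as
this test, matching the homoscedastic t used throughout that work — and
because pooling versus pairing is not specified, both the pooled and the
per-protein paired variant are reported.

Knockdown proteome shifts use spike-in referenced SILAC:
log2(KD/NT) = log2((H/L)_NT / (H/L)_KD), category shifts via the rank
kernel.

## iCLIP (`protloc.iclip`)

Reads are demultiplexed on an exact 5-nt barcode inside the 12-nt prefix
WWW·XXXXX·NNNN; the 3+4 random nucleotides form the 7-nt UMI (the leading
three drawn from {A, T} per the degenerate W code). Zero barcode
mismatches are allowed — the upstream tool's tolerance is not published,
and exact matching keeps the partition property trivially true. Crosslink
sites are the nucleotide 5' of the cDNA insert: position = start − 1 on
the plus strand and position = end on the minus strand (0-based half-open
throughout). PCR duplicates collapse by identical (position, UMI);
replicate tracks merge by positionwise summation.

**Density clustering.** For an interval of crosslink sites define its
*cohesion* as the minimum density (summed count / spanned nucleotides,
end − start in half-open coordinates — a single site has length 1) over
all of its prefixes and suffixes, itself included. An interval is a
cluster exactly when its cohesion strictly exceeds that of every strictly
containing interval on the same (chrom, strand) track; it is then the
maximal interval for all density thresholds in (min_density, max_density],
with max_density its own cohesion and min_density the largest cohesion
among containing intervals — the threshold at which it merges upward. The
track-wide root has min_density 0 and infinite stability fold, matching
the reference Paraclu implementation, which prints the top-level cluster
with minimum density 0; an isolated peak on an otherwise empty track is
therefore callable. Reported clusters satisfy sum ≥ 10, length ≤ 200 nt
and fold ≥ 2 (the published parameters; "minimal density increase 2" is
read as the stability fold max_density/min_density ≥ 2). Because the
published counts are flat peak lists while the cluster family is nested,
overlapping survivors are resolved by keeping the higher fold, ties broken
by shorter then leftmost.

The implementation computes this definition exactly with O(n²) vectorized
prefix/suffix-minimum and containment-maximum tables per (chrom, strand)
rather than by the classic weakest-boundary splitting recursion: on gapped
tracks the recursion can miss family members that straddle a split point
(a constructed counterexample exists), whereas the table form is
definition-faithful. The test suite verifies exact agreement with a
literal brute-force enumeration on random tracks. Memory is O(n²) per
strand track; tracks in the hundreds of thousands of distinct sites per
chromosome would need chunking, which is out of scope at the scales
generated here.

**Downstream.** Control (e.g. GFP-only) peaks are subtracted with
any-overlap, strand-aware semantics (bedtools intersect −v). Target genes
are genes with ≥ 1 specific site overlapping any exonic or intronic
region; a peak spanning two genes is assigned to both and flagged
ambiguous. Region distributions assign each peak by its midpoint — the
rule for boundary-spanning peaks is not published — with a 5'TOP window
of 15 nt downstream of the TSS taking precedence (the motif spans roughly
6–12 pyrimidines; the window is configurable). Metaprofiles sum
strand-oriented 1-nt offset bins around landmarks, normalized to track
library size per million.

## Imaging (`protloc.imaging`)

The polarization index is

    PI = ‖ r̄_RNA − r̄_cell ‖ / Rg_cell,

with r̄_RNA the intensity-weighted centroid of the transcript signal,
r̄_cell the nucleus centroid, and Rg_cell the root-mean-square
(intensity-weighted) distance of the signal from the nucleus centroid.
The printed source formula repeats the x-term where the y-term is meant;
the evident intent is implemented. PI ∈ [0, 1] (Jensen), is invariant
under rigid motions and global unit changes, and is undefined (flagged
NaN) when all signal sits on the nucleus centroid. An unweighted variant
sits behind a flag; whether pixels are thresholded before the centroid is
a caller decision via the `pixels_from_images` helper's cutoff.

Compartment signal ratios are log2 of area-normalized summed intensity,
protrusion over body, with zero-signal compartments capped at a
configurable ±10 and flagged. Co-localization uses greedy one-to-one
matching by increasing distance with index tie-breaks (the reference
plugin's internal rule is unpublished); the result is order-independent.
Particle density is the per-frame count in the mask over mask area,
averaged across frames.

## Synthetic data (`protloc.simulate`)

Generators define the study conditions the tests run under:

- **Counts**: negative binomial parameterized by mean and dispersion
  (dispersion 0.1, log-normal gene means around 200) — the standard
  overdispersed RNA-seq model; the source states none. The planted
  category (80 of 5,000 genes, log2 shift 1.0 split symmetrically across
  fractions) mirrors a ribosomal-protein-sized category at the observed
  shift scale.
- **Ratio panels**: Normal(delta, 0.3) per sample for enriched features,
  Normal(0, 0.3) otherwise, 6 samples — the cross-line design.
- **Pulsed SILAC**: two reciprocally labeled replicates with per-replicate
  ratio noise sd 0.25; nascent nuclear fraction 0.8 versus old 0.4 with
  near-zero membrane share for the planted set, Dirichlet noise
  (concentration 150) that collapses to exact fractions in degenerate
  plantings.
- **iCLIP**: one pseudo-chromosome (10 kb default), uniform sampling
  within planted cluster intervals, uniform background, PCR duplication by
  resampling existing (position, UMI) molecules within their own library
  — the simplest mechanism that exercises deduplication.
- **Spot fields**: isotropic Gaussian scatter at nucleus centroid +
  displacement with log-normal intensities.

Same seed ⇒ byte-identical outputs; every generator emits a TruthRecord
(seed, parameters, planted members) sufficient to score recovery.

What the generators deliberately do **not** model: sequencing or
alignment error, sequence-content bias, crosslink-site sequence
preference, non-uniform within-cluster shapes, isoform structure,
batch effects across cell lines, correlated protein complexes, or
non-Gaussian FISH spot clustering. Passing tests therefore demonstrate
correctness of the statistics and the pipeline plumbing under the stated
models, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Simulation-based tests use 5,000-gene count tables, 2,000-feature panels,
1,000-protein SILAC tables, 12,000-read iCLIP runs on a 10 kb
pseudo-chromosome, and 200-replicate Monte-Carlo loops; these sizes give
stable statistics while keeping the whole suite fast on a single CPU.
Calibration checks allow the nominal rate plus three Monte-Carlo standard
errors. Float comparisons between the clustering and its brute-force
oracle are exact-by-construction (identical integer-derived operands).
Degenerate inputs are handled explicitly rather than by exception:
all-tied rank tests, zero-variance t rows, zero SILAC intensities,
all-zero labels, zero-signal masks, and crosslinks falling off chromosome
ends each have a documented flag or drop path.

## Known limitations

- The clustering's O(n²) tables bound practical track sizes (roughly 10⁴
  distinct sites per chrom/strand on desktop memory).
- Real-data mode consumes pre-aligned coordinates; no aligner or BAM
  ingestion is provided.
- The 2D enrichment tests dimensions marginally; no joint null is fitted.
- Per-line significance on single-replicate lines is not computable and
  not attempted — only the cross-line meta-analysis is.
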