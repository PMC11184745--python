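# Methods

## Data model

Contact maps are stored densely per chromosome (one symmetric float
matrix of raw counts), with trans contacts kept only as per-chromosome-
pair totals — the only trans quantity any analysis here consumes is the
inter-chromosomal contact fraction. Coordinates are 0-based half-open
throughout; interval overlap always means at least one shared base pair.
The native file format is sparse triplet text (either global bin indices
or `chrom start chrom start count`) with a two-column chrom.sizes
sidecar; a dense whitespace matrix reader exists for small inputs.
Working resolutions follow the usual layering: 100 kb for compartments
and entropy, 50 kb for insulation/TADs, 10 kb for loops; a `coarsen_map`
helper aggregates 50 kb maps to 100 kb so one simulation can serve two
layers (diagonal entries are corrected for the mirrored-pair convention
when fine off-diagonal pairs collapse onto the coarse diagonal).

## Balancing and O/E

Balancing runs a symmetric Sinkhorn iteration to per-bin weights that
give the balanced matrix equal (unit) row sums over unmasked bins;
zero-marginal bins are masked (weight NaN), never imputed. Defaults:
relative residual tolerance 1e-6, 1000 iterations; non-convergence
returns the map unbalanced with a warning carrying the residual. The
expected model for O/E is the per-chromosome, per-diagonal empirical
mean of the balanced matrix over unmasked pairs, with no smoothing —
the simplest model that makes the per-diagonal O/E mean exactly 1.
Because balancing reweights chromosome ends, O/E varies within a
diagonal even on a pure-decay matrix; only the per-diagonal mean is
pinned. Depth manipulation draws without replacement (multivariate
hypergeometric across cis pixels and trans totals), preserving symmetry
and integer counts exactly.

Reproducibility between maps follows the GenomeDISCO construction: each
cis matrix is row-normalized to a random-walk transition matrix,
smoothed by t walk steps (default t = 3, a deliberate default with no
claim of equivalence to any particular published parameterization), and
scored as 1 minus the L1 difference of the smoothed matrices per
mutually unmasked bin, averaged over chromosomes.

## Disorder metrics

P(s) curves average balanced or raw contact frequency in logarithmic
genomic-distance bins (defaults 20 kb–50 Mb, 500 bins; empty bins are
missing, not zero). The Jensen–Shannon divergence between two curves
renormalizes both over the jointly non-missing bins and uses natural
logarithms, so 0 ≤ JSD ≤ ln 2.

Von Neumann entropy takes the Pearson correlation matrix of the
log2-transformed contact matrix, clips its eigenvalues at zero (they are
nonnegative analytically; tiny numerical negatives occur), normalizes
them to sum 1 and returns −Σ λᵢ ln λᵢ with 0·ln 0 := 0. The log
transform uses a pseudocount, log2(M + 1), exposed as a parameter, since
raw zeros otherwise have no logarithm; masked bins are removed before
the correlation, not imputed, because imputation would inject spurious
order. On the packaged simulation the entropy responds primarily to
sampling noise (noisier maps score higher, and the bounds ln n / 0 are
attained at the identity-correlation and rank-1 limits); at the default
desk-scale depth the cross-stage ordering is dominated by the zero
pattern of the deeper-contrast stages rather than by their structure, so
per-stage VNE values in the pipeline summary should be read as a noise-
sensitive descriptive statistic, not as a calibrated disorder ranking.

## Compartments

E1 is the first principal component of the per-chromosome Pearson
correlation matrix of the O/E map — computed on the centered correlation
matrix, because the first eigenvector of the raw correlation matrix can
collapse to an all-positive mode on structureless maps. Correlating O/E
(rather than raw balanced counts) is the field convention and is the
default; the sign is fixed per chromosome so that positive-E1 bins
(class A) have the higher mean TSS density, "gene density" being
operationalized as TSS count per bin. Chromosomes with fewer than 10
unmasked bins are masked. Strength AB/(AA+BB) is computed over all cis
pairs (a saddle-corner variant is available through the saddle output);
computing it on O/E makes it depth-invariant, which cross-stage
comparison after downsampling requires. The saddle ranks bins by E1
genome-wide into 50 near-equal groups with no extreme-bin trimming
(parameter exposed); corner summaries average the outermost 10 % of
groups. Peaks straddling an A/B bin edge count toward both labels,
matching ≥1-bp overlap semantics. Switch categories are the per-bin
joint labels of two profiles; the expression association assigns each
gene the category of its TSS bin and compares B2A vs A2B fold-changes
with a two-sided rank-sum test.

## Insulation and TADs

The insulation score of bin i sums balanced contacts between the w bins
upstream and the w bins downstream (window default 500 kb = 10 bins at
50 kb; the score is log2 of the sum over the chromosome mean of defined
sums). Scores are missing where the window leaves the chromosome or at
least half its bins are masked. Chromosome-mean (not genome-mean)
normalization keeps chromosomes comparable in aggregated profiles.
Boundaries sit at negative-to-positive zero crossings of the delta
vector (mean score over delta_window = 2 bins right minus left), kept
when the local delta swing reaches strength_min = 0.1 — Crane-style
defaults adopted as this package's own choices, exposed as parameters.
TADs are the strictly-inter-boundary intervals of ≥ 3 bins (150 kb);
boundary bins belong to no TAD and gaps under 3 bins stay unassigned,
which is how two boundaries closer than 3 bins are suppressed. TAD
sharing requires reciprocal overlap ≥ 75 % of both intervals with
one-to-one best-reciprocal matching. Boundary variability takes every
bin used as a boundary in any stage, drops bins unscored in any stage,
ranks by the across-stage SD of insulation (ties broken by genome
order), keeps the top k (default 1000), standardizes rows and clusters
hierarchically (complete linkage, Euclidean) — the clustering choices
are this package's, made where only a heatmap package was named
upstream.

## Loops

The caller is an intentionally simplified single-resolution variant of
the donut-filter approach: for each candidate pixel (separation 20 kb–
2 Mb, both bins unmasked) four neighborhood expectations — donut,
lower-left square, horizontal and vertical stripes (peak half-width 2,
outer half-width 5) — are computed as the neighborhood's observed/
expected ratio times the pixel's distance expected, and the raw count is
Poisson-tested against the largest of the four. Three filters combine:

1. BH-FDR within log-spaced distance strata (default 8) at the nominal
   FDR (default 0.1);
2. fold floors (observed ≥ 2× donut and lower-left, ≥ 1.5× stripes);
3. a family-wise specificity gate: a Bonferroni threshold at level
   `max_fwe` (default 0.02) over all tested pixels.

The gate exists because an FDR-level procedure alone admits at least one
genome-wide false call on a structureless map with probability close to
its nominal level; the gate caps that probability near `max_fwe`,
making the caller a high-specificity detector. Detection power is set
by depth: on the default 5 Mb / 10 kb fixture, ~5e6 contacts make an
intensity-4 single-pixel loop clear all three filters over nearly the
whole separation range (the analytic Poisson detection curve guided the
default). Significant pixels merge by 8-connectivity; the loop is
reported at the count-weighted centroid with the component's best
q-value. Poisson on raw counts models no overdispersion, so under
multiplicative rate noise the caller reports genuinely noise-elevated
pixels as focal contacts — the same caveat Poisson-based callers carry
on real data; the pipeline therefore simulates its loop layer at a
milder rate noise (σ = 0.1) than the coarser layers (σ = 0.2). No
equivalence with Juicer Tools' HiCCUPS is claimed anywhere.

APA averages the O/E window (flank 10) over loops and scores center ÷
mean of the lower-left corner block (size ⌈flank/2⌉), the Juicer
convention. Loop sharing allows both anchors to shift at most one bin,
greedily matched best-q first. Anchor classes use 1-bin anchors with
promoter-over-enhancer precedence when an anchor overlaps both.

## Elements and TF occupancy

Active enhancers are H3K27ac peaks with zero overlap against H3K4me3
peaks; promoter regions are symmetric TSS ± 3 kb windows (strand
ignored — the definition is symmetric), clipped to chromosome bounds;
active promoters additionally require FPKM strictly above 1. Anchor
enrichment compares the fraction of TF peaks overlapping any anchor
with n_rand draws of length-matched regions placed uniformly on the
matched anchor's chromosome (random regions may overlap each other);
the empirical p-value is floored at 1/(n_rand+1). Gene occupancy
classes follow a best-loop rule: over all loops touching a gene's
promoter region, the gene is "both" if any loop has both anchors bound
(≥1-bp TF-peak overlap), else "one", else "none"; genes with no
promoter-connecting loop are "no_loop". Expressed means FPKM ≥ 2.
Pairwise comparisons (both vs one, one vs none) use two-sided rank-sum
tests with BH correction across the fixed pair set.

## The synthetic generator

A `StructureSpec` fixes: power-law decay (1+d)^(−α) with α = 1 by
default (the canonical contact-probability slope; the exponent is
exposed because curve shapes, not an absolute slope, are what cross-
stage comparisons read); a per-bin A/B label track whose like pairs are
scaled by (1+c) and unlike pairs by (1−c); TAD blocks multiplying
wholly-intra-TAD pixels by a factor ≥ 1 (boundary bins belong to the
left TAD); focal loops multiplying single pixels by intensities ≥ 1;
total depth; i.i.d. mean-one log-normal rate noise; and a trans
fraction distributed over chromosome pairs by size product. Counts are
Poisson draws of the upper triangle, mirrored; with σ = 0 the expected-
rate map is the infinite-depth limit in which planted factors are
recovered up to balancing edge effects and the planted signal's own
contribution to the distance expected (TAD factors are strongly diluted
at short range, where most pairs are intra-TAD).

Default desk-scale conditions: 2 chromosomes × 20 Mb at 50 kb for
compartment/TAD work (contrast 0.6, nine boundaries per chromosome at
factor 3, ~1.2e6 contacts, σ = 0.2, trans fraction 0.10); a 5 Mb
segment at 10 kb with 30 intensity-4 loops and 5e6 contacts for loop
work. The three-stage series treats adult as the base, fetal at 0.9×
structure with 12 % of bins label-flipped, and nascent at 0.3×
structure, 18 % flipped relative to fetal, lower depth and a higher
trans fraction (0.15) — the relaxed-early, consolidating-late pattern,
with flips applied to whole compartment blocks because megabase-scale
switches are what eigenvector calling can resolve. Depth is equalized
across stages by hypergeometric downsampling to the minimum before any
cross-stage metric.

Annotations pair each loop with a gene TSS inside its first anchor
(remaining genes uniform), place TF peaks on each anchor independently
with probability 0.6 plus background peaks, put H3K4me3 at every TSS
and H3K27ac at second anchors plus background, bias ATAC peaks 4:1
toward A bins, and draw log-normal FPKM (σ = 1) whose mean is
multiplied by 3 for genes in A bins and by the occupancy multipliers
(default 4 / 2 / 1 for both / one / none) of the gene's loop.

What the generator does not emulate: genomic distance-dependent bias
(GC, mappability — balancing is therefore nearly a no-op on simulated
maps), overdispersion beyond log-normal rate noise, structured trans
contacts, nested TAD hierarchies, anchor-width variation, or any
polymer physics. Passing tests therefore demonstrate the estimators'
correctness and calibration on well-specified planted signal, not
performance on the biases of real libraries.

## Numerical choices and degenerate inputs

0·ln 0 := 0 everywhere an entropy or divergence is summed; eigenvalues
clipped at zero before normalization; correlation of a constant matrix
is rejected with a diagnostic; empty maps are rejected by ratio
metrics; a fully masked chromosome yields an empty O/E with a warning;
a boundary or loop too close to a chromosome end is skipped and
counted. Ties in the variability ranking break by genome order; the
greedy matchers (TAD sharing, loop sharing) order candidates by best
score, then coordinates, so results are deterministic. Every stochastic
routine takes an explicit seed; the pipeline derives all stage seeds
from the single config seed, making two runs byte-identical.

## Problem sizes

The packaged study conditions are desk-scale by design — 400-bin
chromosomes and a 500-bin loop segment — chosen so that every layer's
estimators operate in a regime where their planted signal is clearly
recoverable; the full suite and the end-to-end pipeline each complete
in well under a minute on one CPU.

## Known limitations

Single-resolution loop calling without overdispersion modeling;
per-chromosome (not genome-stitched) eigenvectors; no sub-compartment
(multi-eigenvector) calling; no nested-domain hierarchy; trans contacts
carried only as totals; the VNE cross-stage caveat above; and interval
operations hold all intervals in memory (fine at the intended scales).
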