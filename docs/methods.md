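# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Coordinates and formats

All coordinates are 0-based half-open (BED native); 1-based inputs are
converted at the reader boundary. Matrices travel as HiC-Pro-style text
(bin-id COO TSV plus a bin-definition BED); loops as BEDPE with anchor1
genomically upstream; tracks as bedGraph TSV. Strand affects only the TSS
position (minus-strand genes: TSS = gene end), never interval overlap.
Trans-chromosomal records are rejected everywhere — the analysis is
cis-only.

## Contact-map normalization

Bins whose marginal count is zero or below the 2nd percentile of nonzero
marginals are masked before balancing (Newton-type balancing is unstable on
near-empty rows; production pipelines filter similarly). Balancing uses the
true Knight–Ruiz inner–outer Newton iteration (inexact Newton with
conjugate-gradient inner solves); a plain alternating-scaling Sinkhorn
iteration serves as the *test oracle only*. The common row sum is fixed to
1 rather than left on an arbitrary scale so downstream values are
deterministic. Convergence tolerance 1e-6 on the max row-sum deviation;
non-convergence raises an error carrying the final deviation.

The expected profile E(d) is the plain per-diagonal mean of balanced values
over unmasked pairs, zeros included, with no distance smoothing. This
forces the mean O/E of every diagonal to be exactly 1, which the tests
assert to 1e-9. Duplicate pair records are counted as given — deduplication
belongs to the upstream alignment stage.

## Compartments

The working matrix is the Pearson correlation of O/E columns over unmasked
bins (masked bins are dropped and re-inserted as NaN in the output track).
The eigenvector for the largest eigenvalue comes from a dense symmetric
solver — at desk-scale resolutions the matrix is at most a few thousand
bins, so power iteration buys nothing. A degenerate leading eigenvalue
(e.g. X = I) triggers a warning since the vector is then arbitrary. The
sign is oriented so the track correlates non-negatively with a reference
density (gene density by default; Pearson correlation); A := positive after
orientation. Zero-variance or orthogonal references leave the sign as
computed, flagged. Resolution is a parameter — there is no single canonical
eigenvector resolution, so the choice is exposed rather than hard-coded.

## Insulation and TADs

I(i) sums balanced values over the w/2 × w/2 rectangle joining the w/2 bins
upstream of i with the w/2 bins downstream (window 1 Mb by default; the
window must be a multiple of the resolution). Scores are NaN where the
rectangle leaves the matrix and at masked bins; masked pixels inside the
rectangle contribute 0. A `use_raw` flag preserves the alternative reading
in which raw rather than balanced counts are summed. Boundaries are local
minima with prominence ≥ 0.1 × median(I) — a threshold chosen for stability
under Poisson noise and exposed as a parameter; chromosome ends never
qualify. Consecutive boundaries become TADs; spans under 3 bins are dropped
to avoid degenerate domains from adjacent minima. Corner-score (Arrowhead
style) TAD calling is deliberately not implemented: insulation-derived TADs
are the supported caller, so TAD counts are not comparable to counts from
corner-score callers.

Cross-condition TAD matching: a Control TAD is *common* iff it overlaps
exactly one KO TAD, that KO TAD overlaps exactly one Control TAD, and both
flanking boundary regions (the gap, possibly zero-length, between
neighbouring TADs) overlap between conditions. The three output classes
partition both input sets.

## Loop calling

Four neighborhoods around pixel (i, j), parameterized by the inner
exclusion radius p and outer radius w (defaults 1 and 3 bins at 25 kb,
scaled ×2.5 / ×5 at 10 / 5 kb):

* donut — the (2w+1)² square minus the (2p+1)² core;
* lower-left — the w × w block down-left of the pixel minus its p × p
  corner;
* horizontal — rows within ±p, columns p < |dj| ≤ w;
* vertical — the transpose of horizontal.

The local expectation for a neighborhood is λ = E(|i−j|) × (Σ balanced
values / Σ distance-expected values) over its pixels, masked and off-matrix
pixels excluded from both sums. Significance is a Poisson upper-tail test
on the raw-count scale (λ de-scaled by 1/(w_i w_j) and compared with the
raw observed count), BH-corrected per neighborhood across all tested
pixels. The heavier lambda-chunked machinery of GPU loop callers is not
reproduced; global per-neighborhood BH is simpler and its calibration is
verified directly on null simulations. Tested pixels: both bins unmasked,
j − i ≥ max(2, 2w+1) bins, separation ≤ 10 Mb.

A pixel is enriched when the observed/λ ratio is ≥ 1.5 for **all four**
neighborhoods (the 50 %-more rule is binding: a significant pixel at ratio
1.49 is rejected) and all four adjusted q < 0.10. Enriched pixels are
clustered by 8-connectivity; each cluster yields one loop at its max-O/E
pixel, ties broken by smallest (i, then j). The q of a call is the minimum
adjusted p over the four neighborhoods; single-pixel clusters must pass it
at the stricter 0.01. Cross-resolution merging prefers the finest
resolution's call; a coarser loop is kept only when its anchors overlap no
finer call.

Loop-set algebra: merging collapses connected components of the
both-anchors-overlap relation to the member with the highest called
intensity (idempotent); the non-redundant union keeps all primary loops
plus the secondary loops overlapping none of them, so
|union| = |primary| + |secondary-specific| exactly.

Quantification reads the O/E at the stored peak pixel on any condition's
map; when the map resolution differs from the calling resolution the pixel
is re-localized to the max O/E within ±1 bin to absorb the re-binning
shift (re-localizing at the same resolution would only add selection noise
to the fold change). Fold changes use a pseudocount of 0.5 × the minimum
positive O/E of the loop list in both numerator and denominator, which
prevents division blow-ups on sparse maps. Single-pixel fold changes are
Poisson-noisy: at 10⁶ pairs per 20 Mb the per-loop count at long
separations is ~5–30, so intensity fold changes rank reliably only on
deeper maps (the tracking test uses 8 × 10⁶ pairs, where the planted
coupling dominates).

## CTCF peak dynamics

Peaks are merged across conditions as connected components of the overlap
graph (union interval, per-condition signals, zero where absent). The
classifier is purely a fold-change threshold: Up iff FC > 1.5, Down iff
FC < 1/1.5, boundary values Neutral; the classes partition the set and
re-classification is a fixed point. The pseudocount guarding zero signals
is the 1st percentile of positive signals (pooled over conditions), so it
is negligible for realistically spread (log-normal) peak strengths.
Promoter enrichment compares the promoter fraction of Up peaks against
Down peaks by default (an Up-vs-all-background comparator is available);
zero cells get a Haldane 0.5 correction in the ratio, flagged, while the
chi-square runs on the raw table. RPGC coverage normalization is
re-implemented as per-bin coverage scaled to genome-wide mean 1 with no
effective-genome-size correction — the synthetic genome is a single
chromosome. Enhancer ATAC signals are length-scaled: mean signal ×
length/1000.

## Integration statistics

FPKM = pairs × 10⁹ / (transcript length × total pairs). Expressed genes:
max FPKM ≥ 0.5 in either condition. DE calls use q < 0.05 strictly
(q = 0.05 exactly is not DE) with the sign of log2 FC. Loop-anchored genes:
promoter (TSS ± 1 kb) overlaps either anchor; one link per (gene, loop)
pair, so a gene bridging several loops contributes several combinations,
and genes with no link form the "outside"/rank-0 group. Rank groups: stable
ascending sort (ties by genomic coordinate, then input order) split into k
contiguous groups, sizes differing by at most 1, larger groups first —
n = 5027, k = 4 gives sizes 1257/1257/1257/1256 and n = 2359 gives
590/590/590/589. Group comparisons are two-sided Mann–Whitney against the
external baseline (rank 0) when given, else against rank 1; the exact
method is verified against full permutation enumeration for small samples.
The anchored/outside × up/down chi-square runs without continuity
correction by default (Yates behind a flag). Convergent motif pairs: a '+'
motif in the upstream anchor and a '−' motif in the downstream anchor;
the pair count is the product. EP loops: one anchor overlaps a non-promoter
enhancer interval, the other a promoter window, either orientation;
enhancers inside promoter windows count as promoters (logged).

Published worked-example arithmetic is reconstructed by running these same
operations on inputs built from the published counts: 4666 + 2239 loops
with 1878/1881 cross-overlaps give non-redundant unions of 5027 (KO
primary) and 5024 (Control primary); 3836/4666 = 82.2 % CTCF-anchored;
1551/4666 = 33.2 % convergently motived; 21,593 + 27,772 + 1,770 = 51,135
classified peaks. The chi-square of the published contingency table
[[221, 115], [165, 171]] is ≈ 19.09 (p ≈ 1.2e-05 by the direct formula);
the p-bound printed alongside that table in the source analysis
(< 2.5e-07) is not reproducible from the table itself, so the
formula value is reported.

## Synthetic data: what it emulates and what it does not

Expected pixel intensity: μ_ij ∝ (|i−j|+1)^(−α) · exp(β c_i c_j) ·
τ^[same TAD] · loop kernel, calibrated so the expected upper-triangle mass
equals the target pair count; counts are Poisson (a negative-binomial
option exists for robustness experiments). Defaults: 20-Mb chromosome,
25-kb bins, 10⁶ pairs per condition, α = 1, plaid strength β = 0.3 with
geometric compartment blocks of mean 2 Mb, TAD sizes 10–80 bins with
intra-TAD multiplier τ = 2, 20 loops with peak enrichment λ ∈ (3, 6) and
√λ on the 8-neighborhood (so enriched pixels form small clusters),
separations 10–80 bins. Planted loops are intra-TAD and
compartment-coherent ("loop domains"), as CTCF loops overwhelmingly are in
mammalian maps; this also keeps their absolute counts detectable at the
default depth, which cross-domain placement would not be.

CTCF: a peak at every loop anchor plus 160 background peaks; per-peak
baseline occupancy log-normal (median 50 fragments, log-sd 1 — real peak
strengths span orders of magnitude); true fold changes drawn from class
mixtures (Up: exp(N(ln 2, 0.2)), Down its reciprocal, Neutral
exp(N(0, 0.05)) at proportions 0.42/0.54/0.04 mirroring the published
class split), with each peak's recorded class being the category its
realized fold change belongs to, so the manifest is self-consistent with
the classifier's own thresholds. Counts are gamma-Poisson with mixing CV
0.1 (the biological-CV convention: var = m + (0.1 m)²), drawn as two
biological replicates per condition — matching the duplicate-ChIP design
of the kind of study emulated — whose mean is the peak signal; setting the
dispersion to 0 gives the exact noiseless limit. KO loop strength follows
log2 λ_KO − log2 λ_Ctrl = γ × (mean anchor CTCF log2 FC) + N(0, 0.2) with
γ = 0.5. Convergent motifs at 60 % of loop anchors. Expression: 2000
genes, 15 % with promoters planted inside loop anchors, baseline FPKM
log-normal, true log2 FC = 0.4 × the anchoring loop's intensity log2 FC,
observed as 3-vs-3 replicates with N(0, 0.2) noise, log2 FC and q from
Welch t + BH; genes are placed 3:1 in the A compartment so eigenvector
sign orientation is testable.

Not emulated: read-level sequencing artifacts, restriction-fragment or
ligation biases, trans contacts, copy-number variation, multiple
chromosomes, and real mouse coordinates. Passing tests therefore shows the
operations are correct and calibrated under the generative model's
assumptions — not that the pipeline's thresholds are optimal for any
particular real dataset. Under the default 3-vs-3, σ = 0.2 expression
design almost no gene reaches q < 0.05, so the DE-contingency stage of the
simulated pipeline usually reports a degenerate table and is skipped; the
contingency machinery itself is exercised on constructed tables.

## Problem sizes

Tests and the acceptance script run at the generator defaults above:
800-bin maps, 5 seeds × 2 conditions for loop recovery, 10 null seeds for
false-loop calibration, 20 runs of the 5027-loop coupling analysis, and
8 × 10⁶-pair maps for the intensity-tracking check. The full simulated
pipeline completes in a few seconds on one CPU.

## Known limitations

* TAD counts are caller-specific; only insulation-derived TADs are produced.
* Loop-intensity fold changes from single peak pixels are depth-limited
  (see above); aggregate (cluster- or APA-style) quantification is out of
  scope.
* The promoter definition is symmetric TSS ± 1 kb throughout, chosen for
  consistency with the loop-anchored-gene rule; annotation tools with
  asymmetric promoter windows will classify borderline peaks differently.
* The log2Ratio of promoter proportions depends on the comparator
  (Up-vs-Down by default, Up-vs-background behind a flag); no claim is
  made that either reproduces any particular published value, whose exact
  denominator is unstated.
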