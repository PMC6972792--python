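# Methods

This note documents the models, parameter choices and numerical decisions
behind `pioneerscan`, and what the synthetic benchmark does and does not
establish about real data.

## Coordinate and signal model

All intervals are 0-based half-open; overlap means ≥ 1 shared base
(no minimum overlap fraction is imposed anywhere). Threshold comparisons
are inclusive on the keep side — e.g. mean mappability exactly 0.8 is
kept. Intervals are clipped, never wrapped, at chromosome ends; resize
operations drop intervals whose width would become non-positive.

Signal tracks are dense per-base float arrays per chromosome. Count
tracks carry a library size; normalized counts are tags per 10⁷
(`raw × 10⁷ / library`). Ratio tracks (mappability, conservation,
methylation) have no library size and are never normalized.

## Motif model

A PWM is a width × 4 probability matrix with background base frequencies
and a log-odds threshold. Scores are natural-log odds; a pseudocount of
10⁻³ is added to probabilities (and background) before taking logs so no
column is −∞. `N` bases score as the column minimum, which makes
N-containing windows effectively fail thresholds. Minus-strand matches
are scored with the reverse-complemented matrix (background complemented
too) and reported in reference coordinates; overlapping opposite-strand
matches at one locus are both kept.

The shipped 12-bp surrogate PWM (consensus `AAAGAGGAAGTG`, GGAA core at
offset 5) is a test/simulation stand-in for an ETS-factor consensus; real
analyses supply their own PWM file (plain text: one header line
`>name core_offset=K threshold=T`, then width rows of four
probabilities). Its secondary column probabilities rotate by position so
that single mismatches form a fine ladder of score penalties — this is
what lets the generator realise arbitrary target scores (below). The
GGAA-core offset is a PWM annotation because the core is fixed
biologically, not positionally.

The CGGAA (methylatable) classification flags matches whose sense-strand
word carries `C` immediately 5′ of the GGAA core. Motifs with another
match within 150 bp are excluded from the methylation analysis set — the
same radius as the homotypic pair analysis — because ChIP signal there
could derive from the unmethylated neighbor.

Word-matched controls: for each distinct word among target motifs with
multiplicity k, `min(k, available)` no-signal motifs with the identical
word are sampled uniformly without replacement (seeded); shortfalls are
reported per word. When words determine scores, the control score
distribution therefore equals the target distribution exactly.

## Stand-in peak caller

The original tooling behind factor/region peak calling is heuristic and
proprietary-formatted; downstream analytics depend only on the peak-set
*semantics* (fixed-size vs stitched regions, the stringent gate), so this
module states its own: candidate windows on a stride of half the window
size, greedy non-overlap resolution keeping the higher count (leftmost on
ties), Poisson upper-tail p-value of the window count against
max(genome-wide rate, local control rate over 10 windows, control count
in the same window), BH correction across candidates. Stringent peaks
additionally require FDR ≤ 10⁻⁵ and ≥ 15 tags per 10⁷. Region mode calls
150-bp windows, requires ≥ 2-fold local enrichment, and stitches windows
whose centers are closer than 250 bp. Including the same-window control
count in the background guarantees that identical signal and control
tracks yield zero peaks.

Differential regions use summed replicate counts per condition with
library-size exposures and the exact conditional binomial form of the
two-sided Poisson rate test (BH-corrected), gated conjunctively on a
≥ 2-fold normalized change. Counts are rounded to integers symmetrically,
which keeps the procedure exactly antisymmetric under condition swap.
This is a documented stand-in for a negative-binomial replicate model:
with few replicates and planted effects ≥ 2-fold it recovers the same
up/down/unchanged partition, but it does not model biological
overdispersion.

## Accessibility

Tn5 cut positions: plus-strand read start +4; minus-strand read end −5
(half-open). Peaks are summarized by normalized cut counts in 300-bp
peak-centered windows per condition. Clustering is K-means (10 restarts,
seeded, best inertia) on log2(x+1)-transformed counts — the transform and
restart policy are this package's choices; K defaults to 14 and is a
parameter. Clusters are relabeled 1..K by increasing mean pre-induction
accessibility, so de-novo-remodeled clusters sort first.

The remodeling index is defined here as
`log2((post + 1)/(pre + 1))` of normalized window counts (cluster value =
mean over member peaks): symmetric, zero at no change, and bounded near
zero change by the pseudocount. Only the quantity's name is inherited;
the formula is this package's definition.

Footprints are per-bp normalized cut counts in strand-oriented ±100-bp
windows around motif centers, averaged over motifs. Windows are
zero-padded at chromosome ends.

## Motif associations

PWM-to-class correlation is the maximum Pearson correlation of flattened
aligned probability matrices over offsets up to half the shorter width
and both orientations; assignment requires r > 0.85. Per-peak
co-occurrence uses the best-scoring focal match as anchor (leftmost on
ties); a class counts if a member instance lies in the peak ≥ 4 bp from
the anchor center; focal motifs are counted greedily left-to-right with a
6-bp minimum separation. Network nodes and edges are fractions of all
peaks; the second focal node is the fraction of peaks with ≥ 2 focal
motifs.

Homotypic pair distance is the difference of 5′ start coordinates on the
reference strand — chosen so that spacing ≥ 12 bp exactly excludes
overlapping 12-mers; pairs span [1, 150] bp, orientation follows strand
agreement. A pair is bound iff both members overlap a peak, unbound iff
neither does; mixed pairs are excluded. Per-distance enrichment is the
upper-tail hypergeometric probability with population all classified
pairs, successes the pairs at that distance, draws the bound pairs;
significance at P < 0.05, with the 12–50 bp band reported in aggregate.

## Gene assignment

Expressed genes receive a basal regulatory domain of TSS ± 25 kb
regardless of neighbors. Per direction the domain extends to the nearest
gene's basal-domain edge but no more than 250 kb from the TSS (the cap is
anchored at the TSS, following the GREAT convention this rule mirrors),
and never retracts inside its own basal domain; chromosome-end clipped.
Region-to-point distances use region boundaries (0 inside). Assignment
priority: all TSSs within 1 kb; else the union of genes of all eQTL SNPs
within 1 kb; else all genes whose extended domain overlaps the region;
else none. A region within 1 kb of several TSSs is assigned to all of
them.

Cluster expression tests are one-sided (induced > control) paired
Wilcoxon signed-rank over the cluster's unique assigned genes: zero
differences dropped, exact null for n ≤ 25 without ties, normal
approximation with tie correction otherwise; clusters with fewer than 3
genes are reported NA. Stars at 0.05 / 0.01 / 0.001.

## Binding prediction

Features per mappability-filtered motif: log-odds score; mean
conservation over the motif; one binary flag per co-motif class with an
instance centered 6–100 bp from the motif center; pre- and post-induction
accessibility as tags per 10⁷ in 50-bp motif-centered windows. Label:
overlap with a stringent peak. The candidate universe is all filtered
motifs (not a peak-matched subsample).

Models maximize the Bernoulli log-likelihood with a ridge penalty of
10⁻⁶ on non-intercept coefficients (keeps separable training halves
finite) by iteratively reweighted least squares to gradient max-norm
10⁻⁸, at most 100 iterations. The train/test split is an exact random
half, unstratified, seeded, and shared across all predictor sets in a
comparison. AUC is computed from the threshold-swept ROC curve and equals
the pairwise-concordance (Mann–Whitney) statistic with ties counting ½.
Higher-order interaction terms are deliberately excluded. The default
nested sets are sequence-only, +pre-ATAC, +pre+post-ATAC.

## Synthetic benchmark

Defaults (the frozen `benchmark_config`): 2 Mb genome over 2 chromosomes
at GC 0.41; 2000 planted motifs in slots ≥ 500 bp apart, clear of the
blacklist and low-mappability regions (both planted as fixed 2-kb
blocks); site classes 25% de-novo-remodeled candidates, 15%
pre-accessible, 55% never-bound, 5% lost partner sites; ATAC libraries
10⁶ cuts.

Planted log-odds scores are drawn from a truncated normal (mean 10,
SD 2, lower bound 6.5) and realised by a mismatch-descent construction:
starting from the consensus, mutable positions (outside the GGAA core and
the CpG-determining base) are visited in random order and the mismatch
whose penalty best consumes the remaining deficit is applied, with
overshoot capped at 0.35 so every planted motif clears the scan
threshold. 20% of primary motifs are forced to the CGGAA variant; half of
those are methylated.

Binding is Bernoulli with
`P(bound) = σ(0.2 + 0.8·(score − 10) + 0.12·log2(1 + pre-amplitude))`,
multiplied by the suppression factor (default 0.25) for methylated
motifs; never-bound and lost-class sites are unbound by construction.
"Remodeled" truth is de-novo class AND bound, recorded post hoc, because
binding is stochastic. The realized bound fraction among scanned motifs
is ≈ 20%, matching the order of what genome-wide consensus-site
accounting shows for this factor class.

Accessibility: Gaussian cut bumps (SD 60 bp) of 600 expected cuts at
accessible sites; bound de-novo sites gain 600 cuts post-induction; lost
sites drop to background post-induction; a multiplicative footprint dip
of 0.4 over the motif span (±2 bp) at bound, currently accessible motifs
(homotypic partners included). The uniform background rate absorbs the
remainder of the 10⁶-cut library target, so planted amplitudes are exact
in expectation. ChIP: background 5×10⁻⁴/bp plus Gaussian bumps (80 tags,
SD 40) at bound sites; the control track is background only.
Conservation: Beta(1.5, 8) background with +0.3–0.4 at bound motifs —
informative but weaker than accessibility. Methylation ratios: Beta(0.7,
0.7) at background CpGs, ≈ 0.8–0.95 at methylated CGGAA cores, ≈
0.02–0.15 at unmethylated ones.

Homotypic partners are co-planted downstream of bound sites at spacings
uniform on 15–45 bp (rate 0.9 — sized so each of the 31 spacing values
carries enough bound pairs for the per-spacing hypergeometric test to
have power at α = 0.05) and of never-bound sites at 12–150 bp (rate
0.35). Partner-class motifs (RUNX/GATA/Ebox surrogates) are planted
upstream at 14–80 bp, at rate 0.6 for below-median-score bound motifs and
0.15 otherwise, making the co-motif feature informative especially at
low-affinity sites.

Genes (60, 85% expressed) get log-normal control expression; genes whose
extended regulatory domain contains a remodeled site get a 1.8-fold
induced increase with log-normal noise (SD 0.15). At benchmark site
density nearly every domain contains a remodeled site, so *all* clusters
test significant for expression induction — the benchmark demonstrates
the test's sensitivity, not the cluster-contrast pattern of real data.
eQTLs are 60 random SNPs linked to 1–2 expressed genes each.

All randomness derives from one seed through named sub-streams, so
outputs are byte-identical across runs with the same configuration.

### What the benchmark does not emulate

Read-level data (alignment is out of scope; tracks are emitted as cut/tag
counts), Tn5 sequence bias and fragment-length structure, biological
overdispersion between replicates, copy-number variation, realistic
genome composition (repeats, CpG islands, gene clusters), and the
correlation structure of real enhancer landscapes. Passing the benchmark
shows the *procedures* are implemented correctly and recover planted
structure at realistic effect sizes; it does not validate biological
conclusions on any real genome.

## Problem sizes and numerical choices

The test suite and acceptance script run the benchmark at 2 Mb / 2000
motifs and verify the interval engine against per-base boolean oracles on
10-kb chromosomes (1000 random instances), the scanner against exhaustive
rescoring of a 50-kb genome at widths 4–12, and the hypergeometric tail
against exact combinatorics for populations ≤ 60 — sizes at which the
brute-force oracles are exact and fast. K-means uses 10 restarts;
logistic IRLS tolerance is 10⁻⁸; BH correction is used for every
multiple-testing step. Ties are broken leftmost (peak windows, anchors)
or by stable sorts (cluster relabeling) so every pipeline stage is
deterministic at fixed seeds.

## Known limitations

The stand-in peak caller is not a drop-in for published callers on real
data (no input auto-scaling, no local filtering cascades, no CNV
correction). The differential test assumes Poisson counts. The pipeline
orchestrator always starts from the simulate stage; analyses of external
data compose the library functions directly (see `examples/`). bigWig
binary I/O is out of scope — convert to bedGraph first.
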