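# Methods

This note documents the models and procedures implemented in
`embryotime`, the synthetic cohort generator they are validated
against, and the numerical and design choices that were genuinely open.

## Pseudo-time model

Embryo profiles are compared by d(i,j) = 1 − Pearson(log2(xᵢ+1),
log2(xⱼ+1)) on size-factor-normalized counts (size factor = library
total / median total; every embryo then sums to the median library
size). The log transform stabilizes the high-abundance maternal genes
that would otherwise dominate the correlation; distances on
untransformed normalized values are available behind a flag.

Clustering is classic PAM k-medoids on the precomputed distance matrix:
a greedy build phase followed by best-improvement swaps until the total
within-cluster distance stops decreasing. All tie-breaks are by lowest
index, so fits are deterministic; on instances with ≤ 12 samples the
build is restarted from every sample, which makes the local search
reliably optimal (verified against exhaustive medoid enumeration).
`select_k` maximizes mean silhouette width (ties → smallest k).

The lineage tree is the minimum spanning tree over Euclidean distances
between cluster medoid log-profiles. Each embryo x in cluster a is
projected onto the incident edges: s = ⟨x − m_a, m_b − m_a⟩ / ‖m_b −
m_a‖², the edge maximizing s is kept, and s is clamped to [0, 1]. When
the tree is a simple path (any node of degree ≥ 3 is an error — these
cohorts span a single developmental continuum), cluster path position
plus signed s gives a total order. Orientation is anchored
biologically: the path-end cluster with lower mean summed expression of
an early-zygotic marker set is called youngest. Remaining ties break
lexicographically by embryo id.

Unfertilized eggs decay their maternal mRNA (partially) but never
activate zygotic transcription, so they combine a late pseudo-time
position with silent early markers. `call_fertilization` flags an
embryo as unfertilized when its summed normalized marker expression is
below 1.0 *and* its rank percentile exceeds 0.25; low-marker embryos
below that cutoff are merely young (indeterminate). Both thresholds are
exposed.

The pipeline clusters twice. The full-cohort pass uses
silhouette-selected k; on default synthetic cohorts this picks k = 2–3,
and that coarse resolution is exactly where the rank-quartile fertility
rule is coherent — at fine k the handful of unfertilized eggs form
their own path-end cluster whose silent markers would win the
orientation rule. The fertilized-only re-analysis uses a finer default
k = 9 (with stepwise k−1 fallback while the medoid MST is not a path),
giving the stage resolution the cluster-wise statistics need.

## Differential expression

Two clusters are compared by a two-condition negative-binomial exact
test on per-group count sums, conditioning on the total K = k_A + k_B:
p = Σ P_A(a)P_B(b) over all splits a + b = K whose joint probability
does not exceed the observed split's, normalized over all splits,
computed in log space. Group means are the pooled (null) per-gene
normalized mean scaled by each group's summed size factors; variances
add α·q²·Σs² with per-gene dispersion α. K = 0 returns p = 1 by
convention and is flagged.

Dispersion is a moment estimate α_g = max(0, (s² − m)/m²) using the
pooled *within-group* variance (between-group signal would inflate
dispersion exactly for the genes being tested), with a least-squares
trend α(m) = a0 + a1/m over genes with positive estimates; the larger
of moment and trend is used per gene (conservative). Fold changes are
log2((mean_B + 0.1)/(mean_A + 0.1)); the pseudocount (exposed) keeps
onset genes finite. BH correction runs over all tested genes;
significance defaults to padj < 0.01 and |log2FC| > 1, both first-class
parameters (a padj < 0.1 variant is in scope for onset-wave
comparisons).

## Maternal decay

Maternally deposited transcripts are genes averaging > 1 normalized
count over the 10 earliest-ranked embryos of the fertilized-only
ordering. Decay DE restricts the exact test to that set between the
youngest cluster and the cluster at major-wave onset (default: 60% of
the way along the path); degraded = padj < 0.01 and log2FC < −1.
Degraded genes are ranked by first-cluster mean (ties by gene id) and
split into four near-equal quartiles; per (cluster, quartile) the mean
over embryos of the quartile's summed normalized counts is reported,
plus the last/first-cluster ratio per quartile. With decay rates
independent of deposit the four ratios agree; rank-coupling rates to
deposit makes the top quartile decay fastest — both behaviors are
exercised by the generator switch `couple_decay_to_abundance`.

Small clusters leave a power-selection artifact: weakly deposited genes
need stronger decay to reach significance, tilting the bottom-quartile
ratio down. The quartile benchmark therefore runs at 400 embryos with
k = 6, where decay-DE power is ≥ 97% and the artifact is inside the
0.1 ratio-spread band.

## Sex analysis

Sexing uses one female determinant (Sxl-like) and one male marker
(msl-2-like): undetermined when both normalized counts are below 1.0
(markers not yet transcribed), else female iff log2((f+0.1)/(m+0.1)) >
0. An exact zero log-ratio with both markers above the floor is called
male and flagged.

Sex-differential time-course testing fits, per gene on log2(norm+1),
the full model intercept + sex + natural-cubic-spline(timepoint, df=3)
+ sex × spline, against the reduced model without the sex terms, with
the cluster position along the path as the timepoint and every embryo a
replicate of its cluster. The patsy natural-spline basis spans the
constant, so designs are compared by actual matrix rank; the error
surface fires only when no sex-associated dimension is estimable.
Ordinary F-tests are used without empirical-Bayes moderation. The
pipeline lowers df to (sexed timepoints − 1) when the sexed embryos
span fewer clusters than the requested basis.

Type-I calibration of this test is measured under a stratified null:
labels randomized *balanced within cluster*. Fully independent label
flips leave chance sex-age imbalance inside clusters that co-inflates F
for every age-dependent gene (fractions of p < 0.05 up to 0.09 in
individual cohorts); the stratified null isolates the sex terms and
calibrates at 0.04–0.05.

Dosage compensation is quantified as per-cluster female:male ratios of
summed normalized zygotic (non-maternal) counts, X-linked versus
autosomal, over embryos with determined sex. The two sexing marker
genes are excluded from the sums: their sex bias reflects
sex-determination regulation, not chromosome dose, and in a
2,000-gene synthetic transcriptome a single female-only gene measurably
distorts the X sum (in a ~10k-gene real dataset it would not).

Series smoothing is two-stage: a centered moving average of width 5,
then a local least-squares polynomial of order 2 over the same window,
edges shrinking symmetrically (the order drops with the window). Both
stages reproduce linear signals exactly. The source description of
this smoother is ambiguous about whether the window is 5 per side or in
total; total width 5 is implemented, with `window` exposed.

Marker-set scores are Σ log2(norm+1) over the set's genes (sum of logs,
not log of sum), reported along pseudo-time with a LOWESS trend
(default span 0.3).

## Synthetic cohort generator

The generator emulates the statistical structure these analyses assume,
with every parameter exposed in `SimConfig`. Defaults describe a
120-embryo, 2,000-gene desk-scale cohort: three 1-h collection windows
with incubation offsets covering ages 10–180 min; 15% of embryos
withheld (age inflated beyond the window by an exponential extra term,
mean 45 min); 4% unfertilized; lognormal library depths around 2×10⁴
UMIs; gene-wise gamma-Poisson counts with dispersion α = 0.2 (α = 0
degenerates to a multinomial draw over genes).

Gene programs and kinetics:

- maternal stable (31%), a0 ~ lognormal(log 20, 1);
- maternal decay, intrinsic machinery (30%): a0·e^(−λt) regardless of
  fertilization, λ ~ U[0.012, 0.035]/min (half-lives 20–58 min);
- maternal decay, fertilization-triggered (5%): decays only in
  fertilized embryos;
- zygotic minor wave (6%): onset τ ~ U[35, 75] min, low plateaus
  (ramp U[0.1, 0.4]/min, plateau = 60·ramp);
- zygotic major wave (20%): τ ~ U[110, 140] min, ramp U[0.2, 0.7] — a
  massive gene cohort whose transcripts nevertheless leave the library
  maternal-dominated through 3 h, as in real embryos;
- zygotic transient (7.8%): Gaussian pulse after onset (the smooth
  rise-and-fall shape is a modeling convenience);
- one Sxl-like marker (X-linked, female-only after τ ~ U[85, 100]) and
  one msl-2-like marker (autosomal, 10:1 male:female), both strongly
  expressed with gene-specific dispersion 0.02 — tightly regulated
  genes are far less noisy than the genome-wide default, and the
  marker-pair sexing rule needs that separation.

X-linked zygotic genes carry a 2× female factor before compensation;
males ramp linearly from 1× to 2× between `compensation_onset_min`
(default 165) and 180 min. Zygotic genes are drawn autosome-biased (X
weight 0.05 vs 0.17 for maternal genes): the early zygotic gene set of
*Drosophila* is genuinely X-underrepresented, and at desk scale this
also keeps the library-composition bias of size-factor normalization
(female libraries carry the X excess, deflating all female normalized
values by 2–4%) inside the recovery bands.

Unfertilized eggs are modeled as long-retained eggs, age ~ U[150, 180]
min since laying. This is a deliberate design choice: the fertility
filter works by spotting advanced intrinsic maternal decay without
zygotic expression, and a freshly laid unfertilized egg is
indistinguishable from a freshly fertilized embryo in principle. The
retained-egg model gives the filter the separability it is specified to
have; cohorts where unfertilized eggs are laid fresh would show reduced
sensitivity at the young end.

What the generator does **not** emulate: spatial expression gradients,
per-nucleus resolution, mixed maternal+zygotic transcript pools for the
same gene (real data cannot distinguish the molecules; here the classes
are disjoint by construction), amplification artifacts, batch effects,
or ERCC spike-ins. Passing benchmarks therefore demonstrate correct
recovery of the modeled structure, not robustness to those phenomena.

## Benchmarks and their sizes

`embryotime.benchmarks` runs each stage against the generator's truth.
Study sizes are chosen so sampling noise is small against the measured
effect, and are the package's own validation design: ordering and
fertility at the default 120 embryos; DE calibration/power on 2,000
null and 550 power genes at 15 vs 15; decay quartiles at 400 embryos /
k = 6; dosage at 600 embryos / k = 6 with late clusters defined as mean
age > 150 min and ≥ 10 sexed embryos per sex; spline recovery at 300
embryos. The "compensation complete" dosage condition sets the ramp
onset to 60 min because the male ramp reaches parity only at 180 min
exactly — with the default onset no cluster can be fully compensated.

Known limitation: major-wave X genes switch on at the very end of the
observable window and are still ramping at collection end, so their
sex-differential signal is weakly observable at any cohort size; the
spline-recovery benchmark asserts recovery of sex-differential genes
expressed *through* the sexed window (minor-wave X genes and the two
markers) and reports late-onset X recall separately.
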