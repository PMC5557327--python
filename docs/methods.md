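# Methods

This note records the models and conventions `crpevol` implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical details that affect results.

## Gene clusters

A cluster is a maximal run of ≥ 2 family genes on one chromosome in which
every adjacent pair is closer than `max_gap_bp` (default 10 000 bp, the
conventional few-kilobase rule for plant gene families). Two conventions
required a decision:

- **Distance.** "Genomic distance" is taken as the intergenic gap,
  `max(0, next.start − prev.end − 1)` in 1-based inclusive coordinates,
  clamped to 0 for overlapping models. A start-to-start variant is available
  via `distance="start"` for sensitivity analysis.
- **Strictness.** The comparison is strict (`gap < max_gap_bp`): a gap of
  exactly 10 000 bp does not cluster.
- **Within-family only.** Genes of other families lying between members do
  not break a cluster; chaining happens on the family subset, while
  coordinates always come from the full annotation.

The census reports cluster count, clusters with more than two members,
clustered-gene count, and the clustered percentage of the family
(half-up rounding to two decimals, the convention used for every percentage
the package prints).

## Collinear blocks and duplication typing

Homolog pairs (pre-filtered at E-value < 0.01, strict) are placed on a
rank-vs-rank grid per chromosome pair, where a gene's rank is its 1-based
position among all genes of its chromosome ordered by start (ties: end, then
id) — ranks always reflect the full annotation, never a family subset,
because tandem/proximal typing depends on genome-wide adjacency.

Blocks are found by iterated maximum-weight chaining: per orientation
(parallel/antiparallel), dynamic programming finds the longest chain whose
consecutive anchors advance by 1–`max_gap_ranks` ranks on both chromosomes
in the orientation's direction; the best chain (weight first, then earlier
start rank, then parallel before antiparallel, then lexicographically
smallest anchor sequence — a total order that makes extraction
deterministic) is emitted if it has ≥ `min_anchors` anchors, its anchors are
removed, and the search repeats. Defaults `min_anchors=5`,
`max_gap_ranks=25` follow the published MCScanX defaults; the internal
block-probability formula of such tools is deliberately not reproduced —
input pairs are filtered at the alignment level instead.

Duplication classes are assigned with fixed precedence:

1. `wgd_segmental` — anchors any collinear block (WGD and segmental
   duplication are one class; the block evidence cannot separate them);
2. `tandem` — homolog at the adjacent rank on the same chromosome;
3. `proximal` — homolog within `proximal_window_ranks` (default 20, the
   common classifier convention) ranks on the same chromosome;
4. `dispersed` — any other homolog;
5. `singleton` — no homolog.

Within-genome blocks only are used for typing; the same chaining operation
serves cross-genome comparisons.

## NG86 Ka/Ks

For each codon, each of the three positions contributes the fraction of its
three possible single-nucleotide changes that are synonymous to the
synonymous site count S, the remainder to N, so S + N = 3L exactly. Mutations
to stop codons count as nonsynonymous by default (`stop_policy="nonsyn"`);
`"exclude"` removes them from the position's denominator instead (both
conventions appear among NG86 implementations). Pair sites are the average
over the two sequences.

Differences: codons differing at one position are classified directly; at
two (three) positions the synonymous/nonsynonymous step counts are averaged
over the 2 (6) equally weighted mutational pathways, excluding pathways that
pass through a stop codon (with a fallback to including them if all do).

Proportions pS = Sd/S, pN = Nd/N are corrected with the Jukes–Cantor
formula d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 yields an undefined ("null")
distance that propagates as an undefined Ka, Ks or ratio rather than an
exception — such pairs are excluded from density and group tests and counted
in reports.

Significance is a two-sided Fisher exact test on
[[Sd, Nd], [S−Sd, N−Nd]] with fractional entries rounded half-up (the
documented choice of the standard Ka/Ks calculator; a pooled two-proportion
z-test is available via `test="z"`). A pair is called positively (negatively)
selected when the ratio is defined, exceeds (falls below) 1, and P < α
(default 0.05). No multiple-testing correction is applied by default,
matching common practice for this screen; Benjamini–Hochberg can be applied
downstream by the user on the reported p-values.

Ks-based dating filters Ks to (0, 2) — older duplications are saturated and
unreliable — and finds strict local maxima of a Gaussian KDE (Silverman's
bandwidth unless overridden) on a 512-point grid, returned strongest first.

The likelihood-ratio test consumes externally fitted site-model −ln L
values (M0/M7/M8 from codeml or similar; fitting is out of scope):
statistic = 2·Δln L clamped at 0, upper χ² tail with the stated degrees of
freedom. Bartlett's test (scipy) compares Ka/Ks variance across duplication
classes; groups need n ≥ 2 and positive variance.

## Expression divergence

Divergence of a duplicate pair is 1 − ∂ with ∂ the signed Pearson
correlation of raw RPKM profiles across ≥ 3 stages, so divergence lives in
[0, 2] and anti-correlated duplicates are maximally divergent. |r| is used
only for within-cluster coordination tables, whose note-style output
(|r|, stars at P < 0.05 / P < 0.01 from the t-distribution with n−2 df)
mirrors the usual presentation. Both conventions are flag-selectable, as is
a log2(x+1) transform (off by default: raw RPKM). Zero-variance profiles are
skipped and logged, never silently imputed.

Per-class summaries report n, quartiles and median; the class ordering
string joins classes whose medians differ by < 0.05 with "≈".

qPCR fold change is 2^(−ΔΔCt) with replicate Ct values averaged before the
formula. "Standardisation" of profiles to a reference stage is implemented
as per-gene scaling to that stage's value (an interpretation; it is a report
option, not part of any statistic).

## Synthetic data: what it emulates, what it does not

`simulate_genome` plants, on otherwise background chromosomes
(intergenic gaps uniform on [10 001, 50 000] bp, guaranteeing no accidental
clusters under the 10 kb rule; gene lengths uniform on [300, 3000] bp):

- clusters of 2–4 genes with all internal gaps exactly `cluster_gap_bp`;
- tandem arrays of 3 consecutive-rank homologs (fixed length: longer arrays
  would themselves chain into a ≥ 5-anchor self-collinear block and change
  class, making planted truth ambiguous);
- rank-preserving collinear segments across chromosome pairs, with homolog
  runs placed ≥ 26 ranks apart so neighbouring structures can never chain
  into one block.

`simulate_codon_pair` applies one single-nucleotide edit per chosen codon
(synonymous edits at codons with a one-step synonymous neighbour,
nonsynonymous edits avoiding stops), so the planted (Sd, Nd) are recovered
exactly by pathway averaging. It deliberately does **not** model multiple
hits, transition/transversion bias or codon usage — it validates counting,
not evolution; multi-hit codons are exercised by hand-built fixtures in the
tests.

`simulate_expression` draws each pair from a bivariate Gaussian with the
target correlation, then shifts and positively scales per gene to
non-negative RPKM-like values — affine maps that leave Pearson r untouched,
so a noise-free pair hits the target exactly (including r = −1) and the
finite-sample mean tracks the target to Monte-Carlo tolerance. An earlier
exponentiating construction was rejected because it attenuates and
sign-distorts the planted correlation. Independent measurement noise
(`noise_sd`) attenuates the expected correlation by 1/(1+noise_sd²);
recovery tests therefore use noise 0. Real RPKM skew, stage
autocorrelation, and shared-cluster regulation are not modelled —
passing recovery tests demonstrates the statistics are computed correctly,
not that real data will be this clean.

All generators are pure functions of their arguments including the seed;
same seed, byte-identical output files.

## Numerical choices

- Percentages: decimal half-up rounding to 2 decimals (banker's rounding
  would flip printed table values).
- Fisher's table entries: fractional NG86 counts rounded half-up to
  integers; negatives clamped at 0.
- Chain tie-breaks: the total order above; tests verify it against an
  exhaustive-enumeration oracle.
- KDE bandwidth: Silverman's rule; fixed-bandwidth override divides by the
  sample standard deviation to set scipy's covariance factor.
- Degenerate inputs: empty family census, zero-variance Bartlett groups,
  saturated JC proportions, < 3 stages and < 10 Ks values all raise or
  propagate "undefined" explicitly, as documented per function.

## Problem sizes

The validation suites use: a 4-chromosome × 100-gene planted genome
(5 clusters, 4 tandem arrays, 3 collinear segments of 6 anchors); a
{50, 100, 300}-codon × {0..10}² planted-edit grid (363 pairs); 200
expression pairs × 50 stages; 1000 Bartlett replicates (3 × 12 values);
200 random ≤ 12-anchor chaining instances and 500 random 30-gene cluster
instances against brute-force oracles. These sizes give exact recovery or
tight Monte-Carlo tolerances while keeping the whole suite fast.

## Known limitations

- Block finding is greedy iterated best-chain extraction: a reasonable and
  deterministic approximation to production synteny tools, not a
  reimplementation of any specific one (no block E-value model).
- NG86 only; maximum-likelihood codon models (GY94 family), model averaging
  and BEB site identification are out of scope — site-model likelihoods are
  consumed, not fitted.
- Alignments are taken as given (gap columns dropped codon-wise with a
  logged count); no aligner is bundled.
- "WGD" and "segmental" duplicates are a single class; separating them needs
  cross-species dating that is out of scope.
- Expression divergence uses per-stage means; replicate-level variance is
  not propagated into the correlation significance.
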