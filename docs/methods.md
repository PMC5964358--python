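# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Read QC

The three rules run in fixed order: trim → merge → filter.

* **End trimming** scans inward from both read ends and strips bases until
  the first and last retained base have Phred quality strictly above 20.
  Interior low-quality bases survive (they are handled by the
  expected-error filter).  The operation is idempotent and may return an
  empty read, which the merge step then rejects.  An alternative reading —
  truncating at the first low-quality base and discarding everything
  after it — would remove interior segments; the both-ends inward scan is
  the milder rule and is the one implemented.
* **Merging** reverse-complements the reverse read and scores every
  ungapped overlap length from `min_overlap` (default 50) up to the
  shorter read by match count, ties going to the longer overlap.  The best
  candidate is accepted when its mismatch fraction is ≤ `max_mismatch_frac`
  (default 0.1 — a common read-merger default; the underlying study does
  not state one).  In the overlap the higher-quality base wins and the
  merged quality is the max of the pair; posterior quality recombination
  is deliberately omitted as it does not change which reads pass.
* **Filtering** keeps merged reads iff length ≥ 400 (strict "> 399 bp")
  and expected errors `Σ 10^(−Q/10)` strictly below 0.5, so EE = 0.5
  fails.  The QC report satisfies the conservation identity
  `Σ reasons = n_input − n_passed` on every run, by construction and by
  test.

Phred+33 encoding is assumed throughout the FASTQ I/O.

## OTU clustering and the table

Greedy centroid clustering: unique sequences are processed in decreasing
abundance (ties broken lexicographically by sequence) and join the first
centroid with global-alignment identity ≥ 0.97, where identity is
matches / alignment columns (edlib alignment; note that for highly
divergent pairs co-optimal alignments can differ in column count — at the
97% regime the value is effectively unique).  No chimera stage is
implemented: the synthetic fixtures contain no chimeras and chimera
handling belongs to the upstream tools this package does not replace.

Rarefaction draws a multivariate hypergeometric sample per row (exact
without-replacement subsampling), so every retained row sums exactly to
the depth; samples below depth are dropped with a warning.  The default
depth is 5,000 reads/sample.  The core-OTU filter keeps OTUs present in
strictly more than 20% of samples.  "Normalisation" for PCA means
relative abundance followed by log10 with a pseudocount (default 1e-6,
configurable — the choice only shifts the constant floor of absent taxa).

## Diversity

Shannon entropy is reported in bits (log base 2) and Simpson as
`1 − Σ p_i²`, both configurable; these match the QIIME-1 defaults the
field used at the time.  Chao1 is the bias-corrected estimator
`S_obs + F1(F1−1)/(2(F2+1))`, which degrades gracefully to observed
richness when singletons are absent.  The paired week-0/week-12
comparison uses the two-sided Wilcoxon signed-rank with zero differences
dropped (Wilcoxon's original rule rather than Pratt's); fewer than two
nonzero differences is an error, not a p-value.

## Beta diversity and permutation tests

All five distances are bounded in [0, 1]: Bray-Curtis `Σ|x−y|/Σ(x+y)` and
both Jaccard forms are computed on relative abundances; the UniFrac pair
delegates to scikit-bio, with the weighted variant in its normalised form
so it remains comparable to the other four.  Multifurcating trees (e.g.
star trees) are bifurcated with zero-length internal branches first, which
leaves every UniFrac value unchanged.

PCoA applies Gower double-centering and a symmetric eigendecomposition;
negative eigenvalues (non-Euclidean metrics) are reported unmodified and
coordinates are built from the positive part only — no Cailliez/Lingoes
correction, for transparency.  PCA is column-centered and unscaled.
MANOVA on ordination scores uses Wilks' Λ with the standard F
approximation, defaulting to the first two components (the plotted ones).

PERMANOVA uses Anderson's pseudo-F from among/within sums of squared
distances with seeded label permutations and the +1-corrected p-value
`(1 + #{F_perm ≥ F_obs})/(1 + n_perm)`.  Two consequences are worth
stating explicitly:

* with 999 permutations the smallest attainable p is exactly 0.001, so
  split acceptance in the CAG stage tests `p ≤ α`, not `p < α` — a strict
  inequality could never fire at the conventional α = 0.001;
* on 1-D data with Euclidean distance the pseudo-F coincides exactly with
  the one-way ANOVA F, which the tests exploit as an oracle.

## SparCC

The estimator follows the log-ratio variance decomposition
`t_ij = w_i + w_j − 2ρ_ij√(w_iw_j)` and the sparsity approximation that
makes the row sums of `t` linear in the basis variances.  Choices that
matter:

* **Fraction uncertainty.** Per sample, fractions are drawn from
  Dirichlet(counts + 1); the point estimate is the element-wise median
  over `n_draws` (default 20) such draws.  The median is robust to
  occasional degenerate draws.
* **Iterative exclusion.** After each solve, the most-correlated included
  pair with |ρ| above the exclusion threshold (default 0.1) is removed
  from the sums and the system re-solved.  By default this runs to
  convergence rather than a fixed small number of rounds: with
  guild-structured data a large fraction of pairs violates sparsity, and
  stopping after a few rounds leaves the basis variances inflated and the
  between-guild correlations biased around −0.2.  A pair is never excluded
  when either OTU would fall below three included partners, which keeps
  the linear system nonsingular; nonpositive solved variances (a small-D
  degeneracy) zero the affected OTU's correlations with a warning.
* **Significance.** Pseudo-p-values come from full re-estimation on null
  datasets in which each OTU's counts are independently permuted across
  samples — this destroys inter-OTU association while preserving each
  OTU's marginal distribution.  (Resampling whole samples would preserve
  the correlation under test and cannot serve as a null.)  The two-sided
  pseudo-p is `(1 + #{|ρ_null| ≥ |ρ_obs|})/(1 + n_bootstrap)` with 100
  null datasets by default; the undefined diagonal is set to the smallest
  attainable value and should be masked.

Everything is a pure function of (data, seed); draw and null seeds are
spawned from the master seed.

## CAG discovery

The correlation distance is the simple `d = 1 − ρ` (range [0, 2]); the
alternative `√(2(1−ρ))` is a monotone transform that only re-scales merge
heights.  Ward linkage runs on labels in sorted order, making the
dendrogram invariant to input order.  The partition rule is top-down: a
node's Ward split becomes a two-group PERMANOVA on the node's
sub-distance-matrix; the split is accepted iff p ≤ α (default 0.001, 999
permutations) and both children have at least two OTUs, and accepted
children are recursed into.  A consequence of the permutation floor is a
natural resolution limit: a node of 10 OTUs has at most C(10,5)/2 = 126
distinct balanced bipartitions, so the expected tie count alone puts its
minimum achievable p near 0.009 — small guilds inside small nodes are
deliberately not split at α = 0.001.  This is a property of the
acceptance rule, not a bug: it is exactly what prevents noise splits in
homogeneous nodes.

CAG abundance is the sum of member relative abundances, so the CAG table
conserves the core-OTU total per sample to 1e-12.  The network export
writes edges with ρ strictly above the threshold (default 0.4, positive
correlations only; an absolute-value mode exists) and flags CAGs with no
qualifying edge as excluded-from-display.

## Clinical statistics

HOMA indices use the standard Matthews forms (HOMA-IR = FBG·insulin/22.5,
HOMA-β = 20·insulin/(FBG − 3.5)) with glucose in mmol/L and insulin in
µIU/mL; HOMA-β is undefined at FBG ≤ 3.5 and returned as missing.  LOCF
carries the last observed visit value forward and never alters observed
values; a missing baseline excludes the subject.  The paired endpoint
test is the two-tailed paired t; the between-arm comparison is an OLS
ANCOVA `endpoint ~ 1 + baseline + arm` whose arm coefficient and t-based
p are reported.  The CAG–clinical association grid is Spearman's rank
correlation on per-subject week12 − week0 deltas for both sides (computed
values at each endpoint are also accepted by the API); ties get average
ranks, p-values are exact by permutation enumeration for n ≤ 10 and use
the t approximation above, and constant columns are masked as undefined
rather than reported as zero correlation.

## The synthetic-data generator

Log basis abundances are multivariate normal with an exchangeable block
correlation structure: `within_corr` inside a guild, `between_corr`
(default 0) across guilds, unit log-variance by default, and per-OTU mean
log abundances spread with sd `basis_logmean_sd`.  Closing to fractions
and drawing a multinomial of `library_size` reads (default 10,000) per
sample produces exactly the generative world in which basis-correlation
inference is well-posed — that is intentional: recovery tests measure the
estimator, not model mismatch.

Paired cohorts draw week-12 log basis abundances correlated with week-0
within subject (default 0.7, AR(1)-style mixture that keeps the two
timepoints marginally identical and hence exchangeable under a null
effect).  The gut microbiome of an adult is strongly individual, and this
matters quantitatively: with independent timepoints the within-subject
"shift" of every subject is dominated by redraw noise and no plausible
treatment effect is visible in the distance-shift comparison.  Treatment
multiplies the target guilds' week-12 basis abundances by
`2^log2_fold_change` before closure; clinical deltas are
`slope × (guild relative-abundance delta) + N(0, sd)` for coupled
variables and small-drift noise otherwise, around baselines realistic for
a type-2-diabetes-with-hyperlipidemia cohort (e.g. FBG 7.8 mmol/L,
HbA1c 8%).

What the generator does **not** emulate: chimeras and primer artifacts,
taxonomic label realism, over-dispersion beyond the log-normal-multinomial
(no zero inflation), batch effects, or dropout of subjects.  Passing
recovery tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to every failure mode of real
amplicon data.

## Problem sizes

The validation suite runs at desk scale, chosen so that every property is
measurable with comfortable margins: D = 40–50 OTUs, n = 100–200 samples,
50 subjects per arm in cohort tests, 999 permutations where a partition
decision depends on the p-value floor and 99 where only calibration is
being checked, and 100 replicate runs for null-stability rates.
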