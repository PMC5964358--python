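# guildscan

Guild-structured analysis of 16S rRNA amplicon data from paired two-arm
trials: from raw paired-end reads to OTU tables, diversity and ordination
statistics, compositionally corrected co-abundance groups (CAGs), and the
association of CAG changes with clinical outcomes.

## The problem

Gut microbiome intervention trials ask two linked questions: *did the
treatment shift the microbiota*, and *are specific bacterial groups tied to
the clinical response*?  Answering the second question from 16S counts is
statistically treacherous because sequencing yields *compositional* data —
only relative abundances are observed — and closure to a constant sum
induces spurious negative correlation of about `-1/(D-1)` between `D`
otherwise independent taxa.  Ecologically meaningful co-abundance structure
(guilds of taxa that rise and fall together) must therefore be inferred
with an estimator that works on closure-invariant quantities.

## The core method

**SparCC** estimates correlations between *basis* (latent, pre-closure)
abundances from log-ratio variances, which are invariant to closure:

```
t_ij = Var[ log(x_i / x_j) ] = w_i + w_j − 2 ρ_ij √(w_i w_j)
```

Under a sparsity assumption (most ρ_ij ≈ 0), summing over j gives a linear
system for the basis variances `w_i`, from which

```
ρ_ij = (w_i + w_j − t_ij) / (2 √(w_i w_j)).
```

Pairs that violate sparsity are iteratively excluded from the sums and the
system re-solved; count uncertainty is integrated out by a median over
Dirichlet posterior draws of the fractions, and significance comes from
null datasets with each taxon's counts independently permuted.

Core OTUs (prevalence > 20%) are then clustered by **Ward linkage** on the
correlation distance `d = 1 − ρ`, and each dendrogram split is accepted
only if a **PERMANOVA** (999 permutations, α = 0.001) on the corresponding
sub-distance-matrix supports it; the leaves of the accepted-split tree are
the CAGs.  A CAG's abundance is the sum of its members' relative
abundances, compared week 12 vs week 0 by Wilcoxon signed-rank within each
arm, and correlated with per-subject clinical deltas by Spearman's rank.

Around this core the package implements the full supporting pipeline:
three-rule read QC (end-trimming at Q ≤ 20, ≥ 50 bp overlap merging,
length > 399 bp and expected errors < 0.5), greedy 97%-identity OTU
clustering, rarefaction to 5,000 reads/sample, α diversity (observed OTUs,
Chao1, Shannon, Simpson), five bounded β-diversity distances (Bray-Curtis,
binary/weighted Jaccard, unweighted/weighted UniFrac), PCA/PCoA with
MANOVA on scores, per-subject microbiota-shift comparison between arms,
and the clinical-side statistics (HOMA indices, LOCF imputation, paired t,
baseline-adjusted ANCOVA).  A synthetic-data module generates every input
with known ground truth, so each stage is validated by recovery tests.

## Worked example

`examples/sparcc_cags.py` plants 4 guilds of 10 OTUs (within-guild basis
correlation 0.8) in 200 samples and runs the CAG discovery chain:

```
SparCC on 40 OTUs x 200 samples
mean within-guild rho : 0.756 (true 0.8)
mean between-guild rho: +0.011 (true 0)
CAGs found            : 4 (4 guilds were planted)
  CAG1: 10 OTUs, true guild(s) [2]
  CAG2: 10 OTUs, true guild(s) [1]
  CAG3: 10 OTUs, true guild(s) [0]
  CAG4: 10 OTUs, true guild(s) [3]
network edges with rho > 0.4: 180 (within-guild only by construction)
```

The estimator recovers the planted within-guild correlation with mild
attenuation and no spurious between-guild association; the
Ward + PERMANOVA cut finds exactly the planted partition; and every
ρ > 0.4 network edge joins two OTUs of the same guild.  The other scripts
in `examples/` walk through read QC, OTU clustering, α/β diversity,
cohort simulation and the clinical association grid the same way.

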