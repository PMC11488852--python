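# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Differential expression

Counts are filtered at 0.5 counts per million in at least four samples,
the convention for retaining quantifiable transcripts in a two-dozen
sample bulk design. Normalization is a variance-stabilizing stand-in:
median-of-ratios size factors (per-gene geometric-mean reference over
genes with all-positive counts) followed by `log2(count/sf + 1)`. This
is parameter-free and preserves the property the downstream stages rely
on — flattening the mean-variance relationship of overdispersed counts —
without fitting a dispersion model; the test suite checks the flattening
directly (Spearman |r| between gene-wise mean and variance drops from
>0.8 on raw counts to <0.5 after transformation).

Latent structure (batch, platform) is estimated by SVD of the sample-
space residuals after projecting out the genotype design. The number of
components is chosen by permutation-based parallel analysis: each gene's
residuals are permuted across samples (20 permutations), re-residualized,
and a component is kept while its **variance share** exceeds the 95th
percentile of the permuted shares. Shares, not raw singular values, are
compared: a permuted column generally leaves the rank-deficient residual
subspace, so re-residualizing shrinks raw singular values by about
`sqrt((n-p)/n)` and would inflate the selected rank (on pure noise the
share criterion selects zero components ~98% of the time; the raw-value
criterion selected spurious components two-thirds of the time).

Per-gene tests are ordinary least squares on intercept + genotype +
surrogate variables, with residual variances shrunk toward an
empirical-Bayes prior by moment matching on log variances (the prior
degrees of freedom solve `trigamma(d0/2) = var(log s^2) - trigamma(df/2)`
via Newton inversion; infinite prior df when the observed spread is at
or below the sampling floor). The moderated t uses the combined degrees
of freedom. With shrinkage disabled the statistic reduces exactly to the
classical pooled two-sample t, which the suite asserts. Fold-change
orientation is fixed as III^M − Y^M and recorded on the result.

## Co-expression network

The network is unsigned: `a_ij = |r_ij|^beta`, so positively and
negatively co-regulated partners are both captured. `beta` is selected
as the smallest candidate whose connectivity distribution is
approximately scale-free (fit index R^2 >= 0.8) with mean connectivity
>= 0.7; the full fit table is always reported and a flag marks the case
where no candidate qualifies (argmax R^2 is then returned). The
scale-free fit index discretizes connectivity into 10 equal-width bins
and regresses log10 frequency on log10 mean connectivity, unweighted.
The minimum-mean-connectivity rule is a recorded convention for an
ambiguous published criterion, surfaced in the fit table rather than
hidden.

Topological overlap is
`w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)` with
`l_ij = sum_{u != i,j} a_iu a_uj`; the implementation is the matrix form
`A@A - 2A` off-diagonal and is tested against a triple loop at 1e-12.

Module detection is deliberately deterministic: average-linkage
clustering on `1 - w`, cut at the inter-merge height that maximizes
Newman modularity of the partition on the TOM-weighted graph (the
one-cluster partition scores 0, singleton-dominated partitions score
negatively, so the criterion cannot collapse to either extreme). Two
refinements follow when expression is supplied: (1) kME cleanup — each
gene moves to the module whose eigengene it correlates with most
strongly in absolute value, provided |kME| >= 0.6 (chance |r| at two
dozen samples has sd ~0.22, so 0.6 keeps the false-assignment rate per
gene under ~1%), and modules whose mean member |kME| stays below 0.7
dissolve (clusters of mutually selected noise reach ~0.6, genuine
latent-factor modules ~0.9); (2) iterative eigengene merging at
dissimilarity `1 - r < 0.2`. Modules below 30 genes are unassigned.
These parameters (0.2 merge, size 30) follow the published convention;
the cut/refinement machinery replaces the unstated dynamic-tree-cut
variant with a fully specified equivalent. The eigengene is the first
right singular vector of the gene-standardized module submatrix,
sign-aligned to the module mean profile. kWithin is the within-module
adjacency sum; hub ranking breaks ties by ascending gene ID.

## Connection scores and enrichment

`C_i = sum_j a_ij |F_j|` over the seed family, computed for every
non-seed transcript (a transcript's self-adjacency is never used, and
the seed genes are excluded from their own ranking, since the statistic
asks which *other* transcripts covary with the family). Central genes
are the top k = 100 by default; fraction mode inverts a printed
percentage to its count by nearest-integer rounding. Fisher tests use
the conventional two-sided rule (sum of hypergeometric probabilities no
larger than the observed table's). Genes without a chromosome
assignment are excluded from enrichment universes; a fold-change of
exactly zero counts as "not higher in Y^M" in the sign test
(conservative).

## Allele-specific expression

Diagnostic SNPs are heterozygous in every III^M group and homozygous in
every Y^M group; the allele absent from Y^M genotypes is assigned to the
III^M chromosome, and conflicting Y^M homozygotes drop the site with a
log entry. Depths are normalized to fragments per million (x 1e6).
Three rank-sum comparisons are made per site; in the III^M–Y^M and
III–Y^M comparisons the Y^M observation is the summed depth of both III
alleles per group. The default variant is the normal approximation
without continuity correction, which is the unique standard variant
reproducing p = 0.021 (z = 8/sqrt(12)) for complete 4-vs-4 separation —
the configuration the strain-by-batch design produces at fully biased
sites. The exact enumeration variant (p = 2/70 ~ 0.029 in that
configuration) is provided and is the better choice for new data; both
are regression-tested. Monoallelic flags require strictly zero
III-allele reads in every III^M group with positive III^M-allele reads.

## Behavior

ADD = (T_D − T_t)·d with the house fly threshold 12.4 °C (10 °C for the
*D. melanogaster* comparisons); negative values are flagged. Proportion
comparisons use the pooled-variance z without continuity correction
(one- or two-sided is a caller flag; the default is two-sided).

Random effects in the published mixed models (batch, strain) are
approximated by fixed-effect dummy coding in the logistic and Cox fits —
full mixed/frailty estimation is out of scope — so coefficients are
comparable, not identical, to mixed-model fits; with a single batch the
term is dropped with a warning. Competitive fits model whether the blue
male won on the blue male's genotype (or temperature), the shared
condition, their interaction and batch, with type-II likelihood-ratio
χ² per fixed effect; complete separation triggers a flagged, weakly
L2-penalized fallback fit with the χ² table withheld.

The Cox model is implemented in-package (Newton on the partial
likelihood with step-halving, convergence at gradient norm 1e-9, Wald
95% CIs) because the tie-handling switch is part of the contract: Efron
is the default — latencies observed every 10 minutes are heavily tied —
and Breslow is available; without ties the two agree to 1e-8. The fit
is cross-checked against an independent survival package to ~1e-3
(which is that package's own convergence tolerance; the log-likelihoods
agree to 1e-6). Latencies are treated as event times at the grid value;
interval censoring is not modeled.

## Cross-species resampling null

The ortholog-set statistic is the mean log2 fold-change; its null is
10,000 same-size subsets drawn without replacement from the genome-wide
fold-change values, and p is the fraction of subsets *strictly* more
extreme in the stated tail (upper for orthologs of knockdown-upregulated
genes, lower for downregulated; subset sizes come from the ortholog
table, not configuration). The optional (r+1)/(n+1) correction is off by
default to match the plain-proportion definition. Tissue normalization
divides by the per-tissue mean over included genes after excluding zero
values, under-replicated microarray measurements (<4 replicates) and
entries failing platform thresholds, averaging multi-transcript genes
first.

## Synthetic data

The generator emulates the statistical structure the analyses assume:
negative-binomial counts (gamma–Poisson, dispersion 0.05 by default)
with log-normal gene means (log2 mean 6, sd 1.5), per-gene biological
variability of 0.35 on the log2 scale (plausible for inbred lab strains
of whole-head tissue), multiplicative per-gene batch shifts (sd 0.3),
and planted fold-changes applied as `2^(+F/2)` / `2^(-F/2)` to the two
genotype means. Module structure is a per-module latent Gaussian factor
added on the log-mean scale; its loading is scaled by the total
non-latent variance (biological + a count-noise term
`(1/mu + alpha)/ln(2)^2`) so the realized pairwise correlation
approximates the requested latent correlation rather than being
attenuated by counting noise, and loadings carry random signs so the
planted module is a genuinely unsigned structure. Allele depths are
binomial in the III^M groups at the planted bias; latencies are
exponential with group-specific hazards, rounded up to the 10-minute
observation grid and right-censored at the 240-minute (4 hr) window —
150 minutes is the appropriate bound for the *D. melanogaster* assays.
Default behavioral effects are the study's conditions: a Y^M baseline
hazard of 0.00139/min at 22 °C (≈28% mating within 4 hr), a genotype
hazard ratio of 2.92, and strongly reduced mating at 29 °C. All
randomness flows from one integer seed through a counter-based Philox
stream.

What the generator does **not** emulate: read-level artifacts (mapping
bias, positional coverage), gene-length effects, correlated dispersion,
overlapping or nested module structure, informative censoring, or
per-individual frailty. Passing recovery tests therefore demonstrates
that the estimators are correct and calibrated under the assumed
generative model, not that real data meet those assumptions.

## Problem sizes

The recovery and calibration checks run at sizes chosen to make
sampling error small relative to the tested margins while staying
single-CPU friendly: 1,050 genes x 24 samples over 10–20 replicate
seeds for DE power/FDR, 300 genes x 24 samples over 10 seeds for module
recovery, 500 trials over 50 seeds for Cox recovery, 1,000 random gene
sets for the enrichment false-positive rate, and 300 repetitions of a
400-subset resampling null for its uniformity check.

## Known limitations

Exact numeric replication of the published DESeq2/sva/limma/WGCNA
outputs and of mixed-model (glmer/coxme) variance components is out of
scope by design; the stand-ins are documented above and validated by
property, oracle-equivalence and recovery tests instead. Fisher tests
on small families (e.g. 9 genes) are conservative because of
discreteness. The static modularity cut evaluates O(n) candidate
heights with an O(n^2) score each, which is comfortable to a few
thousand genes but quadratic beyond that.
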