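# Methods

`guildflow` implements a guild-based analysis of microbial community
restructuring in repeated-measures fermentation designs: a few donors, a
factorial perturbation (oxygen exposure x dietary-fiber supplementation),
several time points and replicates, profiled by an amplicon (ASV) count
table and optionally accompanied by fermentation chemistry (pH and
short-chain fatty acids, SCFAs, in µM).

## Pipeline

1. **Rarefaction.** Each sample is subsampled without replacement
   (multivariate hypergeometric) to a common depth, default 28,000 reads.
   Samples below depth are dropped with a logged warning rather than
   aborting the run, since batch designs tolerate occasional shallow
   samples. Rarefied row sums equal the depth exactly.
2. **Prevalence filter.** Features detected (count > 0) in strictly more
   than 30% of samples are retained; the fraction of reads they carry is
   reported as coverage. Prevalence is evaluated globally, not per donor.
3. **Repeated-measures correlation (rmcorr).** For every feature pair, both
   variables are centred within donor and the residuals are Pearson
   correlated; the error degrees of freedom are `N − k − 1` for `N`
   observations and `k` donors, with two-sided p from
   `t = r·sqrt(df/(1−r²))`. This is algebraically the signed square root of
   the covariate partial eta squared from an ANCOVA of y on donor + x, an
   identity the test suite enforces to 1e−10 against an independent
   statsmodels fit. Correlations are computed on log-transformed relative
   abundance (half-minimum pseudocount) by default; pairs with zero
   within-donor variance are flagged degenerate (r reported as 0, p = 1)
   and contribute no network edge and unit clustering distance. The donor,
   not donor x treatment, is the blocking subject, matching the pipeline's
   donor-adjustment stance throughout.
4. **Co-abundance network.** Edges are the non-degenerate pairs with
   |r| > 0.5 (strict) and p < 0.05 (raw, not multiplicity-adjusted); node
   weight is mean relative abundance. Exported as edge-list TSV and GraphML.
5. **Guild delimitation.** The correlation matrix becomes a distance
   (`d = 1 − r`, degenerate pairs at 1), clustered with Ward's
   minimum-variance linkage (features sorted lexicographically first so the
   merge order is deterministic). The dendrogram is cut from the root by
   sequential PERMANOVA in feature space: at each internal node whose
   children both have ≥ 2 leaves, the two child clades are compared on the
   node-restricted distance matrix (observations = features, groups = child
   membership) with 9,999 label permutations; the split is accepted when
   p < 0.001, with `p = (1 + #{F ≥ F_obs}) / (1 + n_perm)` so the minimum
   attainable p (1e−4) lies below the threshold. Untestable small children
   and non-significant nodes terminate as guilds, yielding a total
   partition. Guilds are named CAG1, CAG2, … by descending overall
   abundance, and guild abundance is the per-sample sum of member features.
6. **Ordination and community tests.** Bray-Curtis dissimilarities at the
   ASV and guild level feed PCoA (Gower double-centering of −d²/2,
   eigendecomposition, negative axes dropped without Lingoes/Cailliez
   correction) and donor-adjusted aPCoA, which pre/post-multiplies the
   Gower-centered matrix by the residual-maker projection of the donor
   indicator design before eigendecomposition. Treatment structure is
   tested by pairwise PERMANOVA (999 permutations) with permutations
   restricted to donor blocks ("subject-stratified") and
   Benjamini-Hochberg correction across pairs. Concordance between the
   ASV- and guild-level ordinations is quantified by symmetric Procrustes
   superimposition on the first two axes (m², correlation = sqrt(1 − m²))
   with a PROTEST row-permutation test.
7. **Association models.** Per guild, log-transformed abundance is
   regressed on treatment indicators (Control reference) with a donor
   random intercept (REML via statsmodels MixedLM); q-values are BH across
   the full guild x level family. Guild-SCFA models use the same structure
   with both variables z-scored, so the reported standardized coefficient
   is unit-invariant. Chemistry outcomes (pH, individual SCFAs) are fit
   with the same mixed model and all pairwise treatment contrasts adjusted
   by the studentized-range (Tukey) distribution at residual df
   `N − a − (k − 1)` (the donor-as-fixed approximation; Kenward-Roger df
   are out of scope). When REML fails to converge — a real risk with three
   donors — the model is refit with donor as a fixed effect and the rows
   flagged; on balanced designs the two give identical coefficient signs.
   By default association models use all post-0 h samples; the time window
   is configurable.

## Synthetic communities

The generator draws the study design (3 donors x 4 treatments x 4 time
points x 5 replicates = 240 samples) with planted guilds. Latent feature
log-abundance is

    λ_fs = baseline_g + effect_g(trt_s)·ramp(t_s) + donor_g(d_s) + w_g·Z_gs + ε_fs

with a guild-level factor `Z_gs ~ N(0,1)` (loading `w`, default 0.85), a
per-(guild, donor) intercept (sd 0.6), feature noise (sd 0.6), and
`ramp(t) = min(t/24, 1)` so effects are absent in the 0 h inoculum. Counts
are `multinomial(28,000, softmax(λ))` per sample — compositional by
construction, like the data the pipeline targets. SCFAs are per-guild
yields times realised guild relative abundance plus truncated Gaussian
noise; pH falls as `6.7 − 0.6·log1p(total SCFA in mM)`, clipped to
[3.8, 7.2].

The default scenario plants five response phenotypes: a pathobiont guild
(up under oxygen, suppressed whenever fiber is present), three
oxygen-depleted fermenter guilds rescued by fiber, a transitional guild
promoted only by oxygen + fiber, a fiber-only responder, and two neutral
background guilds. Effect sizes (log-fold changes ~1.2–2.2 at full ramp)
and yield constants were fixed once to make the planted pattern clearly
recoverable at this sample size while keeping compositional spillover onto
null guilds below detection: a bloom in one guild depresses every other
guild's relative abundance, so background mass is kept large enough that
these induced coefficients stay within noise. Under the defaults the
fiber arms reach pH ≈ 4.2 while oxygen-only stays near 5.2.

What the generator does *not* emulate: taxonomy, phylogenetic correlation,
read-level error, overdispersion beyond the multinomial, donor-specific
guild composition (donor effects shift guild abundance, not membership),
and mechanistic fermentation kinetics. Passing tests therefore demonstrate
correctness of the statistical machinery on data satisfying the model's
assumptions, not robustness to real-data pathologies such as zero
inflation or strain-level heterogeneity.

## Numerical and design choices

- All stochastic stages consume explicit seeds from a single
  `numpy.random.Generator` lineage; reruns are bit-identical and the
  pipeline manifest records per-stage seeds and SHA-256 checksums.
- PERMANOVA uses the squared-distance decomposition
  `F = (SS_between/(a−1))/(SS_within/(N−a))`; an exact enumeration mode is
  available for small designs and is cross-checked against brute force.
  Tree-cut and pairwise tests keep distinct permutation defaults (9,999
  vs 999), mirroring their different roles.
- The sequential tree cut tests the split that Ward clustering itself
  selected, which makes it anti-conservative on large homogeneous blocks:
  in simulations, exchangeable blocks of ≤ 12 features stay single at
  α = 0.001 while blocks of ≥ 16 tend to over-split. At realistic guild
  sizes (~8–12 features) the procedure is well behaved; users clustering
  much coarser structures should expect some subdivision of large
  homogeneous clades. Sibling-vs-sibling is the comparison at each node
  (not clade-vs-rest).
- Ties in Ward linkage are broken deterministically by pre-sorting feature
  ids; permutation p-values use the (1+x)/(1+n) estimator throughout.
- Degenerate inputs: all-zero samples stay zero under relative-abundance
  conversion; Bray-Curtis between two empty samples is 0 by convention;
  zero-variance guilds are excluded from the FDR family and flagged.

## Problem sizes

The test suite and acceptance script run the full design (240 samples,
~80 features, 8 planted guilds), 10 independent replicates for recovery
medians, 500 null simulations for type-I calibration (199 permutations
each, n = 20), 200 PROTEST draws for null uniformity, and 100/1,000
random instances for the rmcorr and BH oracles.
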