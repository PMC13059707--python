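# guildflow

Co-abundance guild (CAG) analysis of microbial communities under
perturbation, for repeated-measures designs where a handful of donors each
contribute many samples — e.g. ex vivo faecal fermentations exposed to
oxygen stress and dietary-fiber supplementation and profiled by 16S ASV
counts plus fermentation chemistry (pH, short-chain fatty acids).

Microbiome responses to perturbation are often coordinated across sets of
taxa rather than taxon by taxon. `guildflow` groups features into
*guilds* — co-abundance groups that rise and fall together — and analyses
treatment responses at the guild level, while adjusting every step for the
strong between-donor differences such designs carry.

## The method

For features *i*, *j* measured across samples blocked by donor *k*:

1. **Repeated-measures correlation.** Within-donor centering of
   log relative abundances, then Pearson correlation of the residuals:
   r̄ with df = *N* − *k* − 1 and *t* = r̄·√(df / (1 − r̄²)). This removes
   between-donor composition differences that would otherwise masquerade
   as co-abundance.
2. **Guild delimitation.** Distance *d* = 1 − r̄, Ward hierarchical
   clustering, and a sequential top-down PERMANOVA cut (9,999
   permutations, *p* < 0.001 per split) that accepts a dendrogram split
   only when the two child clades differ significantly; the resulting
   clades are the guilds, with abundance = sum of member features.
3. **Community-level statistics.** Bray-Curtis PCoA and donor-adjusted
   aPCoA (the donor design is projected out of the Gower-centered matrix),
   pairwise donor-stratified PERMANOVA with Benjamini-Hochberg correction,
   and Procrustes/PROTEST concordance between ASV- and guild-level
   ordinations.
4. **Association models.** Per guild, log abundance ~ treatment (Control
   reference) with a donor random intercept; guild ~ SCFA models with
   standardized coefficients; pH/SCFA ~ treatment mixed models with
   Tukey-adjusted pairwise contrasts. All FDR control is Benjamini-Hochberg.

A synthetic-community generator reproduces the target study design
(3 donors × 4 treatments × {0, 12, 24, 48} h × 5 replicates = 240 samples,
28,000 reads/sample) with planted guild structure and ground truth, so
every stage is verifiable end to end. See `docs/methods.md` for the model
and its assumptions.

## Worked example

```python
import guildflow as gf

cfg = gf.default_scenario(seed=42)
counts, meta, chem, truth = gf.generate(cfg)

rare = gf.rarefy(counts, depth=28_000, seed=0)
filtered, coverage = gf.prevalence_filter(rare, 0.30)
rel = gf.to_relative(rare)[filtered.columns]
print(f"{filtered.shape[1]} prevalent ASVs carry {coverage:.1%} of reads")

rm = gf.rmcorr_matrix(gf.log_transform(rel), meta["donor"])
d = gf.correlation_distance(rm)
z, order = gf.ward_tree(d)
ga = gf.cut_tree_permanova(z, d, order, seed=0, abund=rel)
print(f"{len(ga.guild_ids)} co-abundance guilds")

guild_tab = gf.aggregate_guilds(rel, ga)
ord_asv = gf.apcoa(gf.bray_curtis(rel), meta, "donor")
ord_cag = gf.apcoa(gf.bray_curtis(guild_tab), meta, "donor")
proc = gf.procrustes_protest(ord_asv, ord_cag, n_perm=999, seed=0)
print(f"ASV/guild ordination concordance: r = {proc.correlation:.3f}, "
      f"PROTEST p = {proc.p:.3f}")

assoc = gf.fit_guild_treatment(guild_tab, meta)
print(f"{(assoc.q < 0.05).sum()} of {len(assoc)} guild-treatment "
      "associations at q < 0.05")
```

prints

```
70 prevalent ASVs carry 100.0% of reads
8 co-abundance guilds
ASV/guild ordination concordance: r = 0.991, PROTEST p = 0.001
10 of 24 guild-treatment associations at q < 0.05
```

The guild inference recovers the eight planted guilds exactly, and the
guild-level ordination is nearly interchangeable with the full ASV-level
one (Procrustes r = 0.991, significant against the permutation null). The
oxygen-bloomed pathobiont guild shows the planted reversal — enriched by
oxygen alone, suppressed when fiber is added:

```
oxygen-bloomed guild CAG4: Oxygen coef +1.39 (q = 4.8e-13),
Oxygen+Fiber coef -1.99 (q = 3.7e-25)
```

and chemistry follows: `gf.fit_chem_treatment(chem, meta, "pH")` reports
the Fiber arm 0.45 pH units below Control (Tukey p = 5.6e-06).

The same pipeline is available from the shell:

```bash
guildflow simulate --seed 42 --out sim/
guildflow preprocess --counts sim/counts.tsv --depth 28000 --min-prevalence 0.3 --seed 0 --out prep/
guildflow guilds --counts prep/filtered_counts.tsv --metadata sim/metadata.tsv --seed 0 --out guilds/
guildflow run-all --seed 42 --out run/        # everything, plus a manifest
```

`run-all` writes every intermediate artifact (TSV/GraphML/Newick) and a
`manifest.json` with parameters, per-stage seeds and SHA-256 checksums —
enough to reproduce the run bit for bit.

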