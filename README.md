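# grapegen

Toolkit for curating and analyzing plant germplasm collections genotyped
with co-dominant markers: nuclear microsatellites (SSR), SNPs, and
chloroplast microsatellites (cpSSR). It covers the full workflow used in
grapevine (and similar clonally propagated crop) diversity studies:

1. **Fingerprinting and duplicate resolution** — allele-length
   harmonization across runs, motif-aware allele binning, and duplicate
   detection with a small allele-mismatch tolerance so somatic variants and
   single genotyping slips still group together.
2. **Diversity statistics** — per-locus expected/observed heterozygosity
   (He = 1 − Σp², Ho), effective allele number (Ne = 1/Σp²), rarefied
   allelic richness (hypergeometric expectation at a fixed gene-sample
   size), fixation index F = 1 − Ho/He, null-allele frequency estimate
   Fnull = (He − Ho)/(He + Ho), polymorphic information content (PIC),
   probability of identity for unrelated individuals and for full sibs,
   and exact/Monte-Carlo Hardy–Weinberg tests.
3. **Distances and trees** — pairwise −ln(proportion of shared alleles)
   distances and UPGMA dendrograms with Newick export.
4. **Population structure** — a Gibbs-sampler admixture model (independent
   or correlated allele frequencies), Evanno ΔK model choice across
   replicate runs, optimal replicate alignment over label permutations,
   and a Q ≥ 0.75 membership rule; AMOVA (Φ_PT with permutation test) on
   the distance matrix.
5. **Parentage** — Marshall-style likelihood ratios (LOD) for
   parent–offspring duos and trios with a genotyping-error mixture model,
   critical LOD thresholds calibrated by offspring simulation, an allele
   mismatch budget, and a half-kinship screen for first-degree pairs.
6. **Maternal lineages** — cpSSR haplotype (chlorotype) assignment by exact
   lookup and maternity designation inside accepted parent pairs
   (chloroplasts are maternally inherited).
7. **Synthetic data** — a generator with known truth (pools, admixture
   proportions, pedigrees, clones, null alleles, genotyping errors,
   maternal cpSSR inheritance) used throughout the test suite.

## Quick start (library)

```python
import grapegen as gg

cfg = gg.SimPopConfig(seed=7, n_pools=2, n_per_pool=25, n_loci=12)
table, truth = gg.gen_population(cfg)

# diversity statistics
stats = gg.stats_table(table, hw_seed=1)
print(gg.panel_summary(stats))
# {'n_loci': 12, 'A': 100, 'mean_na': 8.33, 'mean_ho': 0.72, ...}

# duplicates, distances, tree
report = gg.find_duplicates(table, max_mismatch=2)
dm = gg.psa_distance(table)
print(gg.to_newick(gg.upgma(dm))[:60], "...")

# structure
res = gg.run_admixture(table, K=2, iters=300, burnin=300, seed=17)
print(res.Q.max(axis=1).mean())   # ~0.97 on two well-separated pools

# parentage
off, ped = gg.gen_pedigree(table, 20, seed=13)
freqs = gg.allele_frequencies(table)
crit = gg.simulate_critical_lod(
    freqs, table, gg.SimulationConfig(n_offspring=1000, prop_sampled=1.0),
    seed=5)
assignments = gg.assign_parentage(off, table, freqs, crit, eps=0.01)
```

## Quick start (CLI)

```bash
grapegen simulate --seed 5 --pools 2 --size 30 --loci 12 --out-dir demo
grapegen dedupe demo/genotypes.csv --panel demo/panel.csv --out dups.csv
grapegen stats  demo/genotypes.csv --panel demo/panel.csv --out stats.csv
grapegen tree   demo/genotypes.csv --panel demo/panel.csv --out tree.nwk
grapegen chlorotype demo/cp_genotypes.csv --panel demo/cp_panel.csv --out cp.csv
grapegen run-all config.yaml      # full pipeline from one YAML config
```

Every stochastic stage takes an explicit seed; rerunning the pipeline with
the same config reproduces every numeric output byte-for-byte.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance-level property tests; one
test (`test_snp_sibling_identity_product_consistency`) fails by design,
documenting the source-data inconsistency above. All other tests pass.

See `docs/methods.md` for the statistical models, estimators, defaults and
their rationale.
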