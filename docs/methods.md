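# Methods

Statistical models, estimators and implementation choices. Notation: a
locus has alleles with frequencies p_i estimated by gene counting from
typed diploid individuals; G = 2·(typed individuals) is the gene count.

## Genotype model

Genotypes are unordered diploid allele pairs; a cell is either fully typed
or missing (half-typed calls are rejected at parse time with the offending
accession and locus named). SSR alleles are integer fragment lengths in
base pairs, SNP alleles are nucleotide letters, cpSSR loci are haploid.
Markers carry a category used to route them to stages: cat. 1
(fingerprinting core), cat. 2 (extended diversity/parentage), cat. 3
(SNP support), cat. 4 (chloroplast).

## Curation

- **Harmonization**: per-locus sizing offsets between runs are estimated as
  the mode of (observed − reference) allele differences over shared
  accessions, and subtracted. The mode resists single mistyped references;
  loci where fewer than 80% of comparisons agree with the mode are flagged
  and left unshifted.
- **Binning**: single-linkage clustering of observed sizes with gap <
  spacing (default: the motif length); cluster members snap to the modal
  size (ties to the smallest). Off-ladder singletons survive unchanged.
- **Duplicates**: pairwise allele mismatches are 2 − |multiset
  intersection| per co-typed locus, summed. Pairs within the tolerance
  (default 2 alleles, accommodating somatic variants and one allele slip)
  are linked; groups are the transitive closure, with non-clique groups
  flagged for review. Pairs with fewer than `min_overlap` co-typed loci
  (default 6) are reported but never merged. Group representative: the
  true-to-type member if metadata marks one, else the lexicographically
  first ID.

## Diversity statistics

With sp2 = Σp², sp4 = Σp⁴:

- He = 1 − sp2; Ne = 1/sp2; F = 1 − Ho/He.
- Fnull = (He − Ho)/(He + Ho) — the heterozygote-deficit null-allele
  estimator.
- PIC = 1 − sp2 − Σ_{i<j} 2 p_i² p_j².
- P(ID)unrelated = Σp⁴ + Σ_{i<j} (2 p_i p_j)².
- P(ID)sib = 0.25 + 0.5·sp2 + 0.5·sp2² − 0.25·sp4.
- Rarefied allelic richness: E[# distinct alleles in g genes] =
  Σ_a [1 − C(G − c_a, g)/C(G, g)], computed with log-gamma for stability;
  g defaults to twice the smallest typed-sample size across loci.
- Cumulative P(ID) is the product over loci. Panel equivalence ranks loci
  by ascending per-locus P(ID) and accumulates the product until it falls
  to or below a target.

**Hardy–Weinberg**: biallelic loci get the full exact conditional test
(enumerating heterozygote counts of the right parity; table probability
includes the 2^h factor). Loci with ≥3 alleles use a seeded Monte Carlo
permutation of gene copies (default 10,000 shuffles, p = (hits+1)/(reps+1)).
Verdicts: *** p<0.001, ** p<0.01, * p<0.05, NS otherwise, ND for
monomorphic loci.

Monomorphic loci report He = 0, P(ID) = 1, F/Fnull undefined.

## Distance and trees

d(a,b) = −ln(PSA), PSA = shared alleles / (2 × co-typed loci), with
multiset sharing (a homozygote shares one allele with a heterozygote
carrying it). Pairs below `min_overlap` co-typed loci (default ⌈L/2⌉) are
NaN; PSA = 0 would be infinite and is instead capped at −ln(1/(4L)) and
flagged. UPGMA is implemented directly (size-weighted average linkage,
merge height d/2, first-found tie-break at fixed input order, so output is
deterministic); it requires a complete matrix. Newick branch lengths are
height differences; labels with structural characters are quoted. The unit
tests check the implementation against both scipy's average linkage and a
naive O(n³) re-averaging reference.

## Admixture model

Standard Bayesian admixture with K ancestral populations: allele copy
origins Z given memberships Q and pool frequencies P, Gibbs updates

- Z: categorical with P(z=k) ∝ q_k · p_k(allele),
- Q_i ~ Dirichlet(α + origin counts), α updated by a Metropolis random
  walk (uniform prior on (0,10]),
- P: independent model P_k ~ Dirichlet(1 + counts); correlated (F-model)
  P_k ~ Dirichlet(p_anc(1−F_k)/F_k + counts) with ancestral frequencies
  updated by a Dirichlet-proposal Metropolis–Hastings step and drift
  parameters F_k by a bounded logit random walk.

The model evidence proxy is ln P(X|K) ≈ mean(log-lik) − var(log-lik)/2
over kept sweeps (the common harmonic-mean-free estimator used for ΔK
work). K = 1 is computed in closed form. Defaults: 2000 burn-in + 2000
kept sweeps; tests use a few hundred, which is enough for the small panels
there (the Q posterior is sharp when pools are separated).

**Evanno ΔK** = |L(K−1) − 2L(K) + L(K+1)| / sd(L(K)) over ≥2 replicates of
≥3 consecutive K values; the suggested K is the argmax. **Replicate
alignment** finds, per replicate, the column permutation maximizing
agreement G = 1 − ‖A−B‖²_F/(2N) with the running mean via the Hungarian
algorithm (optimal over permutations; scipy's `linear_sum_assignment`),
greedily accumulated over many random replicate orders. **Membership**: an
individual belongs to pool k if Q_k ≥ 0.75 (inclusive), else "admixed".

## AMOVA

One-level AMOVA on squared distances: SS_total = Σ_{i<j} d²_{ij}/n,
SS_within from within-group blocks, variance components with the unequal
sample-size correction n0 = (N − Σn_g²/N)/(g−1), Φ_PT = σ²_a/(σ²_a+σ²_w).
Significance by permuting group labels (p = (hits+1)/(perms+1)). Groups
with fewer than two members are excluded with a warning; pairwise Φ_PT is
available.

## Parentage

Per-locus transition probabilities T (duo: offspring given one parent with
the other gene from the population; trio: offspring given both parents)
follow Mendelian transmission. Genotyping error is modeled as full
genotype replacement by a Hardy–Weinberg draw with probability ε (default
0.01); with q = 1 − ε the likelihoods are

- duo: L1 = q²·T2 + (1−q²)·HW,
- trio: L1 = q³·T3 + q²ε·(T2m + T2f) + (qε² + ε)·HW,

against L2 = HW (random individual); LOD = Σ ln(L1/L2) over co-typed loci.
Mixture weights sum to one, and with ε = 0 an excluding locus drives the
LOD to −∞. Alleles absent from the frequency table enter at the floor
1/(G+1).

**Critical LOD**: offspring are simulated from parents that are present in
the candidate set with probability `prop_sampled` (else drawn from allele
frequencies), with genotyping errors applied; for each offspring the best
candidate pair is found by a two-stage search (single-parent LOD matrix,
top-5 shortlist, all shortlist pairs including self-pairs when selfing is
allowed). The strict/relaxed critical values are the most permissive
thresholds achieving 95%/80% assignment precision among simulated offspring
at or above the threshold. Defaults mirror large-collection practice
(10⁶ offspring, prop_sampled 0.01); tests and the acceptance script use
10⁴ offspring with prop_sampled 1.0 because their benchmark plants all
parents inside the candidate set.

**Assignment** is trio-first: accept if LOD ≥ strict threshold and
Mendelian mismatches ≤ ⌊0.05 × loci compared⌋, else fall back to duos under
the same rules; offspring typed at fewer than 10 loci are skipped, and an
offspring is never its own candidate parent. Loci with Fnull > 0.1 are
excluded from parentage. The **half-kinship screen** reports pairs sharing
≥1 allele at every co-typed locus, allowing ⌊0.05L⌋ failing loci, with a
duo LOD attached.

## Chlorotypes

A chlorotype is the exact combination of fragment lengths at four cpSSR
loci, mapped to letters A–H by a lookup table (a literature-derived default
ships with the package; custom maps load from CSV). Any missing cp locus or
unmatched combination yields "n.d.". Within an accepted trio, if the two
parents carry different chlorotypes and the offspring matches exactly one,
that parent is the mother; same-chlorotype parents or any "n.d." member
give "undetermined"; an offspring matching neither parent is a "conflict"
(impossible under strict maternal inheritance).

## Synthetic data generator

Per-locus allele counts are 2 + Binomial(13, 7/13) (mean 9, range 2–15) on
motif-consistent ladders. Pool frequencies follow the F-model
(Dirichlet around ancestral frequencies with drift `divergence`);
individuals are pure or admixed (Dirichlet(α) memberships), genes drawn
per-locus from their origin pool. Optional layers: a null-allele locus
(per-gene-copy null with probability f; one visible copy shows as a
homozygote, two nulls as missing), genotype-replacement errors, uniform
missingness plus an elevated-missingness locus, Mendelian pedigrees with
maternal cpSSR inheritance, and clones differing by ≤2 single-motif-step
mutations. Everything is reproducible from a single integer seed.

## Determinism and numerics

- All stochastic routines take integer seeds; the pipeline derives stage
  seeds from one config seed and reruns are byte-identical.
- Log-space computation wherever products underflow (table probabilities,
  rarefaction, LODs, cumulative P(ID) is fine in double precision down to
  ~1e-300 and is kept as a plain product).
- Test problem sizes (tens of accessions, 8–18 loci, hundreds of MCMC
  sweeps, 10⁴ simulated offspring) are the package's own choices to keep
  the suite under a few minutes on one CPU; library defaults reflect
  full-study scale.

## Limitations

- Admixture sampler has no label-switching moves within a chain; replicate
  alignment handles switching across runs.
- The critical-LOD calibration uses assignment precision rather than the
  Δ-statistic distribution used by some established programs; thresholds
  are therefore comparable in role but not numerically identical.
- No linkage, selection, or demography beyond the F-model in the
  generator; AMOVA is single-level.
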