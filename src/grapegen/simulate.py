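"""Ground-truth synthetic data: founder pools, admixture, pedigrees, clones,
genotyping error, missingness and maternal cpSSR inheritance.

The generator emulates the structure of a mid-size grapevine germplasm
panel: ~127 diploid individuals genotyped at ~36 SSR loci carrying 2-15
alleles each (mean about nine), plus a few dozen biallelic SNP loci, a low
per-locus missing-data rate with one pathological high-missingness locus,
clonal duplicates within a two-allele mutation tolerance, pedigree trios,
admixed individuals drawn from K ancestral pools under the correlated
(F-model) frequency prior, and maternally inherited chloroplast haplotypes.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .chlorotype import ChlorotypeMap
from .genotypes import MISSING, GenotypeTable
from .markers import Category, MarkerDef, MarkerPanel, MarkerSystem


@dataclass
class SimPopConfig:
    seed: int
    n_pools: int = 1
    divergence: float = 0.15          # F-model drift, same for every pool
    n_loci: int = 36
    min_alleles: int = 2
    max_alleles: int = 15
    mean_alleles: float = 9.0
    n_per_pool: int = 127
    admixed_fraction: float = 0.0
    admix_alpha: float = 0.5
    missing_rate: float = 0.02
    high_missing_rate: Optional[float] = None   # applied to the last SSR locus
    error_rate: float = 0.0
    n_snp: int = 0
    snp_maf_range: tuple[float, float] = (0.05, 0.5)
    null_locus_freq: Optional[float] = None     # null allele at the first SSR locus
    motif_length: int = 3
    n_cp_loci: int = 4

    def __post_init__(self):
        for name in ("admixed_fraction", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0,1]")
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence must be in (0,1)")
        if not self.min_alleles <= self.mean_alleles <= self.max_alleles:
            raise ValueError("infeasible allele-count distribution")


@dataclass
class TruthSet:
    """Per-individual generative truth for cross-module checks."""

    pools: dict[str, int] = field(default_factory=dict)        # pure pool of origin
    q_matrix: Optional[np.ndarray] = None                      # admixture proportions
    individuals: list[str] = field(default_factory=list)
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)  # child -> (mother, father)
    clone_groups: dict[str, int] = field(default_factory=dict)
    chlorotypes: dict[str, str] = field(default_factory=dict)
    cp_table: Optional[GenotypeTable] = None
    pool_freqs: Optional[list] = None                          # per locus (K, A)


def _allele_counts(rng, cfg: SimPopConfig) -> np.ndarray:
    """Per-locus allele counts on [min, max] with the configured mean."""
    span = cfg.max_alleles - cfg.min_alleles
    p = (cfg.mean_alleles - cfg.min_alleles) / span
    return cfg.min_alleles + rng.binomial(span, p, size=cfg.n_loci)


def _build_panel(rng, cfg: SimPopConfig) -> tuple[MarkerPanel, list[np.ndarray]]:
    """SSR + SNP panel with motif-consistent allele ladders."""
    counts = _allele_counts(rng, cfg)
    loci, ladders = [], []
    for j in range(cfg.n_loci):
        start = int(rng.integers(34, 100)) * cfg.motif_length
        sizes = start + cfg.motif_length * np.arange(counts[j])
        cat = Category.CAT1 if j < 9 else Category.CAT2
        loci.append(MarkerDef(f"ssr{j + 1:02d}", MarkerSystem.SSR,
                              cfg.motif_length, cat,
                              (int(sizes[0]) - 6, int(sizes[-1]) + 6)))
        ladders.append(sizes)
    for j in range(cfg.n_snp):
        pair = rng.choice(list("ACGT"), size=2, replace=False)
        loci.append(MarkerDef(f"snp{j + 1:02d}", MarkerSystem.SNP,
                              None, Category.CAT3))
        ladders.append(np.sort(pair))
    return MarkerPanel(loci), ladders


def gen_population(cfg: SimPopConfig) -> tuple[GenotypeTable, TruthSet]:
    """Simulate K pools of diploid individuals plus optional admixed ones.

    Ancestral allele frequencies are symmetric-Dirichlet; each pool's
    frequencies are drawn from Dirichlet(p_anc (1-F)/F) (the F-model), and
    individuals are Hardy-Weinberg draws within pools. Admixed individuals
    mix pools according to a Dirichlet(admix_alpha) membership vector.
    """
    rng = np.random.default_rng(cfg.seed)
    panel, ladders = _build_panel(rng, cfg)
    K = cfg.n_pools
    L = len(panel)
    ratio = (1.0 - cfg.divergence) / cfg.divergence

    pool_freqs = []
    for j, ladder in enumerate(ladders):
        A = len(ladder)
        if panel.loci[j].system == MarkerSystem.SNP:
            maf = rng.uniform(*cfg.snp_maf_range)
            p_anc = np.array([maf, 1.0 - maf])
        else:
            p_anc = rng.dirichlet(np.ones(A))
            p_anc = np.maximum(p_anc, 1e-4)
            p_anc /= p_anc.sum()
        if K == 1:
            pool_freqs.append(p_anc[None, :])
        else:
            pool_freqs.append(np.vstack([rng.dirichlet(p_anc * ratio)
                                         for _ in range(K)]))

    n_pure = K * cfg.n_per_pool
    n_admixed = int(round(cfg.admixed_fraction * n_pure / max(1e-12, 1 - cfg.admixed_fraction))) \
        if cfg.admixed_fraction > 0 else 0
    individuals = [f"ACC{i + 1:04d}" for i in range(n_pure + n_admixed)]
    Q = np.zeros((n_pure + n_admixed, K))
    for i in range(n_pure):
        Q[i, i // cfg.n_per_pool] = 1.0
    for i in range(n_pure, n_pure + n_admixed):
        Q[i] = rng.dirichlet(np.full(K, cfg.admix_alpha))

    calls = np.empty((len(individuals), L), dtype=object)
    for j in range(L):
        ladder = ladders[j]
        origins = _sample_origins(rng, Q, 2)          # (N, 2)
        geno = np.empty((len(individuals), 2), dtype=np.int64)
        for k in range(K):
            mask = origins == k
            cnt = int(mask.sum())
            if cnt:
                geno[mask] = rng.choice(len(ladder), size=cnt, p=pool_freqs[j][k])
        is_snp = panel.loci[j].system == MarkerSystem.SNP
        for i in range(len(individuals)):
            a, b = sorted(ladder[geno[i]])
            calls[i, j] = (str(a), str(b)) if is_snp else (int(a), int(b))

    truth = TruthSet(
        pools={ind: int(np.argmax(Q[i])) if Q[i].max() == 1.0 else -1
               for i, ind in enumerate(individuals)},
        q_matrix=Q, individuals=list(individuals), pool_freqs=pool_freqs)

    table = GenotypeTable(individuals, panel, calls, ploidy=2)
    table = _apply_null_locus(rng, table, cfg, ladders)
    table = apply_errors(table, cfg.error_rate, rng)
    table = apply_missingness(table, cfg.missing_rate, rng,
                              high_rate=cfg.high_missing_rate)

    if cfg.n_cp_loci:
        truth.cp_table, truth.chlorotypes = _gen_chlorotypes(rng, individuals, Q, K)
    return table, truth


def _sample_origins(rng, Q: np.ndarray, copies: int) -> np.ndarray:
    """Pool of origin for each of ``copies`` allele copies per individual."""
    c = Q.cumsum(axis=1)
    u = rng.random((Q.shape[0], copies, 1))
    return (u > c[:, None, :]).sum(axis=2).reshape(Q.shape[0], copies)


def _gen_chlorotypes(rng, individuals, Q, K):
    """Pool-specific chlorotype distributions, maternally inherited downstream."""
    cmap = ChlorotypeMap.default()
    combos = list(cmap.rows)
    pool_cp = rng.dirichlet(np.ones(len(combos)) * 0.8, size=K)
    cp_panel = MarkerPanel([MarkerDef(n, MarkerSystem.CPSSR, None, Category.CAT4)
                            for n in cmap.loci])
    calls = np.empty((len(individuals), len(cmap.loci)), dtype=object)
    letters = {}
    for i, ind in enumerate(individuals):
        pool = rng.choice(K, p=Q[i])
        combo = combos[rng.choice(len(combos), p=pool_cp[pool])]
        for j, v in enumerate(combo):
            calls[i, j] = (int(v),)
        letters[ind] = cmap.rows[combo]
    return GenotypeTable(list(individuals), cp_panel, calls, ploidy=1), letters


def _apply_null_locus(rng, table: GenotypeTable, cfg: SimPopConfig, ladders):
    """Mask one allele as a null at the first SSR locus (pathological preset).

    Heterozygotes null/x appear as homozygotes x/x; null/null cells go
    missing — the mechanism behind large apparent heterozygote deficits.
    """
    if not cfg.null_locus_freq:
        return table
    j = 0
    calls = table.calls.copy()
    f = cfg.null_locus_freq
    for i in range(table.n_individuals):
        cell = calls[i, j]
        if cell is MISSING:
            continue
        is_null = rng.random(2) < f
        visible = [a for a, nn in zip(cell, is_null) if not nn]
        if len(visible) == 2:
            continue
        calls[i, j] = MISSING if not visible else (visible[0], visible[0])
    return GenotypeTable(table.individuals, table.loci, calls, table.ploidy)


def apply_errors(table: GenotypeTable, rate: float, rng) -> GenotypeTable:
    """Replace genotypes with random draws from observed allele frequencies."""
    if rate <= 0:
        return table
    calls = table.calls.copy()
    for j in range(table.n_loci):
        genes = [a for i in range(table.n_individuals)
                 if calls[i, j] is not MISSING for a in calls[i, j]]
        if not genes:
            continue
        genes = np.array(genes, dtype=object)
        for i in range(table.n_individuals):
            if calls[i, j] is not MISSING and rng.random() < rate:
                pick = rng.choice(len(genes), size=2)
                calls[i, j] = tuple(sorted((genes[pick[0]], genes[pick[1]])))
    return GenotypeTable(table.individuals, table.loci, calls, table.ploidy)


def apply_missingness(table: GenotypeTable, rate: float, rng,
                      high_rate: Optional[float] = None) -> GenotypeTable:
    """Whole-cell masking at ``rate``; the last SSR locus can run hotter."""
    if rate <= 0 and not high_rate:
        return table
    calls = table.calls.copy()
    ssr_idx = [j for j, m in enumerate(table.loci)
               if m.system == MarkerSystem.SSR]
    high_j = ssr_idx[-1] if (high_rate and ssr_idx) else None
    for j in range(table.n_loci):
        r = high_rate if j == high_j else rate
        if r <= 0:
            continue
        mask = rng.random(table.n_individuals) < r
        for i in np.nonzero(mask)[0]:
            calls[i, j] = MISSING
    return GenotypeTable(table.individuals, table.loci, calls, table.ploidy)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def gen_pedigree(founders: GenotypeTable, n_trios: int, selfing_rate: float = 0.0,
                 error_rate: float = 0.0, seed: int = 0,
                 cp_founders: Optional[GenotypeTable] = None,
                 ) -> tuple[GenotypeTable, TruthSet]:
    """Mendelian offspring of random founder pairs; cpSSR copied from mother.

    Returns the offspring table plus a truth set recording (mother, father)
    edges; with ``error_rate`` > 0 each offspring genotype is replaced by a
    random draw from founder allele frequencies at that rate.
    """
    if founders.n_individuals < 2:
        raise ValueError("need >= 2 founders")
    rng = np.random.default_rng(seed)
    n_f = founders.n_individuals
    offspring_ids = [f"OFF{i + 1:04d}" for i in range(n_trios)]
    calls = np.empty((n_trios, founders.n_loci), dtype=object)
    pedigree = {}
    mothers = rng.integers(0, n_f, n_trios)
    fathers = rng.integers(0, n_f, n_trios)
    selfed = rng.random(n_trios) < selfing_rate
    fathers[selfed] = mothers[selfed]
    clash = ~selfed & (fathers == mothers)
    fathers[clash] = (fathers[clash] + 1) % n_f
    for t in range(n_trios):
        mi, fi = int(mothers[t]), int(fathers[t])
        pedigree[offspring_ids[t]] = (founders.individuals[mi],
                                      founders.individuals[fi])
        for j in range(founders.n_loci):
            gm, gf = founders.calls[mi, j], founders.calls[fi, j]
            if gm is MISSING or gf is MISSING:
                calls[t, j] = MISSING
                continue
            a = gm[rng.integers(0, 2)]
            b = gf[rng.integers(0, 2)]
            calls[t, j] = tuple(sorted((a, b)))
    table = GenotypeTable(offspring_ids, founders.loci, calls, founders.ploidy)
    table = apply_errors(table, error_rate, rng)

    truth = TruthSet(individuals=offspring_ids, pedigree=pedigree)
    if cp_founders is not None:
        cp_calls = np.empty((n_trios, cp_founders.n_loci), dtype=object)
        for t in range(n_trios):
            mi = cp_founders.ind_index(pedigree[offspring_ids[t]][0])
            cp_calls[t] = cp_founders.calls[mi]
        truth.cp_table = GenotypeTable(offspring_ids, cp_founders.loci,
                                       cp_calls, ploidy=1)
    return table, truth


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------

def gen_clones(table: GenotypeTable, n_groups: int, max_mutations: int = 2,
               seed: int = 0) -> tuple[GenotypeTable, TruthSet]:
    """Append clonal copies of ``n_groups`` accessions with planted mutations.

    Each clone differs from its source by at most ``max_mutations`` alleles,
    each shifted by one repeat unit — the somatic-variation regime duplicate
    detection must tolerate.
    """
    rng = np.random.default_rng(seed)
    if n_groups > table.n_individuals:
        raise ValueError("more clone groups than accessions")
    sources = rng.choice(table.n_individuals, size=n_groups, replace=False)
    individuals = list(table.individuals)
    rows = [table.calls[i].copy() for i in range(table.n_individuals)]
    clone_groups = {}
    for g, src in enumerate(sources):
        src = int(src)
        clone_groups[table.individuals[src]] = g
        clone_id = f"{table.individuals[src]}_clone"
        row = table.calls[src].copy()
        n_mut = int(rng.integers(0, max_mutations + 1))
        typed = [j for j in range(table.n_loci) if row[j] is not MISSING
                 and table.loci.loci[j].system == MarkerSystem.SSR]
        for j in rng.choice(typed, size=min(n_mut, len(typed)), replace=False):
            motif = table.loci.loci[j].motif_length or 1
            a, b = row[j]
            which = rng.integers(0, 2)
            shift = motif * (1 if rng.random() < 0.5 else -1)
            pair = (a + shift, b) if which == 0 else (a, b + shift)
            row[j] = tuple(sorted(pair))
        individuals.append(clone_id)
        rows.append(row)
        clone_groups[clone_id] = g
    calls = np.empty((len(rows), table.n_loci), dtype=object)
    for i, row in enumerate(rows):
        for j in range(table.n_loci):
            calls[i, j] = row[j]
    out = GenotypeTable(individuals, table.loci, calls, table.ploidy)
    return out, TruthSet(individuals=individuals, clone_groups=clone_groups)


def concat_tables(a: GenotypeTable, b: GenotypeTable) -> GenotypeTable:
    """Stack two tables over the same panel."""
    if a.loci.names != b.loci.names or a.ploidy != b.ploidy:
        raise ValueError("tables must share panel and ploidy")
    return GenotypeTable(a.individuals + b.individuals, a.loci,
                         np.vstack([a.calls, b.calls]), a.ploidy)
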