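import numpy as np
import pytest

from grapegen import (MISSING, SimPopConfig, concat_tables, find_duplicates,
                      gen_clones, gen_pedigree, gen_population)
from grapegen.markers import MarkerSystem


def test_same_seed_reproduces_population():
    cfg = SimPopConfig(seed=301, n_pools=2, n_per_pool=15, n_loci=8)
    t1, _ = gen_population(cfg)
    t2, _ = gen_population(cfg)
    assert t1.equals(t2)


def test_different_seeds_differ():
    t1, _ = gen_population(SimPopConfig(seed=302, n_per_pool=15, n_loci=8))
    t2, _ = gen_population(SimPopConfig(seed=303, n_per_pool=15, n_loci=8))
    assert not t1.equals(t2)


def test_allele_counts_within_configured_range():
    cfg = SimPopConfig(seed=304, n_per_pool=60, n_loci=20, missing_rate=0.0)
    table, truth = gen_population(cfg)
    for l, locus in enumerate(m.name for m in table.loci
                              if m.system == MarkerSystem.SSR):
        sizes = {a for i in range(table.n_individuals)
                 for a in (table.get(table.individuals[i], locus) or ())}
        assert 1 <= len(sizes) <= cfg.max_alleles


def test_ssr_alleles_sit_on_motif_ladder():
    cfg = SimPopConfig(seed=305, n_per_pool=30, n_loci=6, motif_length=3,
                       missing_rate=0.0)
    table, _ = gen_population(cfg)
    for locus in (m.name for m in table.loci if m.system == MarkerSystem.SSR):
        sizes = sorted({a for ind in table.individuals
                        for a in (table.get(ind, locus) or ())})
        assert all((b - a) % 3 == 0 for a, b in zip(sizes, sizes[1:]))


def test_mean_alleles_near_target():
    cfg = SimPopConfig(seed=306, n_per_pool=127, n_loci=36, missing_rate=0.0)
    table, _ = gen_population(cfg)
    counts = []
    for locus in (m.name for m in table.loci if m.system == MarkerSystem.SSR):
        counts.append(len({a for ind in table.individuals
                           for a in (table.get(ind, locus) or ())}))
    assert abs(np.mean(counts) - cfg.mean_alleles) <= 1.0


def test_missingness_near_configured_rate():
    cfg = SimPopConfig(seed=307, n_per_pool=100, n_loci=20, missing_rate=0.05)
    table, _ = gen_population(cfg)
    ssr = [m.name for m in table.loci if m.system == MarkerSystem.SSR]
    sub = table.subset(loci=ssr[:-1])  # last locus may carry extra missingness
    frac = 1.0 - sub.typed_mask().mean()
    assert abs(frac - 0.05) <= 0.02


def test_null_locus_inflates_homozygosity():
    base = SimPopConfig(seed=308, n_per_pool=120, n_loci=10, missing_rate=0.0)
    nulled = SimPopConfig(seed=308, n_per_pool=120, n_loci=10,
                          missing_rate=0.0, null_locus_freq=0.3)
    t0, _ = gen_population(base)
    t1, _ = gen_population(nulled)
    locus = t0.loci.names[0]

    def ho(t):
        cells = [t.get(i, locus) for i in t.individuals]
        cells = [c for c in cells if c is not MISSING]
        return sum(c[0] != c[1] for c in cells) / len(cells)

    assert ho(t1) < ho(t0) - 0.1


def test_pedigree_is_mendelian():
    cfg = SimPopConfig(seed=309, n_per_pool=30, n_loci=10, missing_rate=0.0)
    table, truth = gen_population(cfg)
    off, ped = gen_pedigree(table, 20, seed=310)
    for child, (mom, dad) in ped.pedigree.items():
        for locus in table.loci.names:
            c = off.get(child, locus)
            gm, gf = table.get(mom, locus), table.get(dad, locus)
            assert any(a in gm and b in gf or a in gf and b in gm
                       for a, b in (c, c[::-1]))


def test_pedigree_without_selfing_has_distinct_parents():
    cfg = SimPopConfig(seed=311, n_per_pool=10, n_loci=6)
    table, _ = gen_population(cfg)
    _, ped = gen_pedigree(table, 50, seed=312, selfing_rate=0.0)
    assert all(m != f for m, f in ped.pedigree.values())


def test_offspring_chlorotype_copies_mother():
    cfg = SimPopConfig(seed=313, n_per_pool=25, n_loci=6)
    table, truth = gen_population(cfg)
    off, ped = gen_pedigree(table, 15, seed=314, cp_founders=truth.cp_table)
    for child, (mom, _) in ped.pedigree.items():
        for locus in truth.cp_table.loci.names:
            assert off is not None
            assert ped.cp_table.get(child, locus) == truth.cp_table.get(mom, locus)


def test_clones_within_duplicate_tolerance():
    cfg = SimPopConfig(seed=315, n_per_pool=25, n_loci=12, missing_rate=0.0)
    table, _ = gen_population(cfg)
    cloned, truth = gen_clones(table, 4, max_mutations=2, seed=316)
    assert cloned.n_individuals == table.n_individuals + 4
    ssr = [m.name for m in cloned.loci if m.system == MarkerSystem.SSR]
    rep = find_duplicates(cloned, ssr, max_mismatch=2)
    groups = rep.multi_member_groups()
    assert len(groups) == 4
    for g in groups:
        assert any(x.endswith("_clone") for x in g)


def test_config_validation():
    with pytest.raises(ValueError):
        SimPopConfig(seed=1, missing_rate=1.5)
    with pytest.raises(ValueError):
        SimPopConfig(seed=1, mean_alleles=20)
    with pytest.raises(ValueError):
        SimPopConfig(seed=1, divergence=0.0)


def test_concat_tables_stacks_and_rejects_duplicates():
    cfg = SimPopConfig(seed=317, n_per_pool=5, n_loci=4)
    a, _ = gen_population(cfg)
    off, _ = gen_pedigree(a, 2, seed=318)
    merged = concat_tables(a, off)
    assert merged.n_individuals == 7
    assert merged.get(off.individuals[0], a.loci.names[0]) == \
        off.get(off.individuals[0], a.loci.names[0])
    with pytest.raises(ValueError):
        concat_tables(a, a)  # duplicate IDs
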