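import itertools
import math

import numpy as np
import pytest

from grapegen import (allele_frequencies, cumulative_pid, hw_exact_test,
                      load_reference_stats, locus_stats, panel_equivalence,
                      panel_summary, stats_table)
from grapegen.diversity import _identity_stats, _rarefied_richness, hw_verdict
from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_stats(cells):
    """Enumerate He/PIC/PIDu/PIDsib/Ho directly from genotype pairs."""
    genes = [a for c in cells for a in c]
    alleles = sorted(set(genes))
    p = {a: genes.count(a) / len(genes) for a in alleles}
    he = 1.0 - sum(p[a] ** 2 for a in alleles)
    pic = he - sum(2 * p[a] ** 2 * p[b] ** 2
                   for a, b in itertools.combinations(alleles, 2))
    pid_u = sum(p[a] ** 4 for a in alleles) + sum(
        (2 * p[a] * p[b]) ** 2 for a, b in itertools.combinations(alleles, 2))
    # P(ID)sib over all genotypes g: sum Pr(g) * Pr(sib has g | one sib has g)
    sp2 = sum(p[a] ** 2 for a in alleles)
    sp4 = sum(p[a] ** 4 for a in alleles)
    pid_sib = 0.25 + 0.5 * sp2 + 0.5 * sp2 ** 2 - 0.25 * sp4
    ho = sum(c[0] != c[1] for c in cells) / len(cells)
    return he, pic, pid_u, pid_sib, ho


def test_statistics_match_brute_force_enumeration():
    rng = np.random.default_rng(91)
    for trial in range(20):
        t = random_table(rng, 10, 1, n_alleles=5)
        cells = [t.calls[i, 0] for i in range(10)]
        he, pic, pid_u, pid_sib, ho = brute_force_stats(cells)
        freqs = allele_frequencies(t)
        row = locus_stats(freqs, t, "L0", hw_reps=1000)
        assert row.he == pytest.approx(he, abs=1e-12)
        assert row.pic == pytest.approx(pic, abs=1e-12)
        assert row.pid_unrelated == pytest.approx(pid_u, abs=1e-12)
        assert row.pid_sib == pytest.approx(pid_sib, abs=1e-12)
        assert row.ho == pytest.approx(ho, abs=1e-12)


def test_pid_sib_by_exhaustive_sib_pair_enumeration():
    """P(ID)sib formula equals direct enumeration over parental genotypes."""
    p = np.array([0.5, 0.3, 0.2])
    alleles = range(3)
    acc = 0.0
    for m1, m2, f1, f2 in itertools.product(alleles, repeat=4):
        prob_parents = p[m1] * p[m2] * p[f1] * p[f2]
        # both sibs draw one allele from each parent, independently
        geno = {}
        for a, b in itertools.product((m1, m2), (f1, f2)):
            key = tuple(sorted((a, b)))
            geno[key] = geno.get(key, 0) + 0.25
        acc += prob_parents * sum(v ** 2 for v in geno.values())
    _, _, _, pid_sib = _identity_stats(p)
    assert pid_sib == pytest.approx(acc, abs=1e-12)


def test_rarefied_richness_against_enumeration():
    """Nar for g=2 equals direct expectation over all gene pairs."""
    counts = [6, 3, 1]
    total = sum(counts)
    # E[#distinct] = sum_a P(allele a appears in a sample of 2 genes)
    expect = sum(1 - math.comb(total - c, 2) / math.comb(total, 2)
                 for c in counts)
    assert _rarefied_richness(counts, 2) == pytest.approx(expect, abs=1e-12)
    # full sample recovers the observed allele count
    assert _rarefied_richness(counts, total) == pytest.approx(3.0)


def test_rarefaction_monotone_in_g():
    counts = [8, 5, 4, 2, 1]
    vals = [_rarefied_richness(counts, g) for g in range(1, sum(counts) + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# closed forms and reference rows
# ---------------------------------------------------------------------------

def test_biallelic_half_frequencies_closed_forms():
    he, pic, pid_u, pid_sib = _identity_stats(np.array([0.5, 0.5]))
    assert he == pytest.approx(0.50)
    assert pic == pytest.approx(0.375)
    assert pid_u == pytest.approx(0.375)
    assert pid_sib == pytest.approx(0.59375)


def test_null_allele_estimator_value():
    he, ho = 0.76, 0.32
    fnull = (he - ho) / (he + ho)
    assert round(fnull, 4) == 0.4074
    ref = load_reference_stats("ssr36")
    row = ref[ref["locus"] == "Vchr14b"].iloc[0]
    est = (row["he"] - row["ho"]) / (row["he"] + row["ho"])
    assert est == pytest.approx(row["fnull"], abs=5e-3)


def test_monomorphic_locus_degenerate_stats():
    t = make_table([[(100, 100)], [(100, 100)]])
    freqs = allele_frequencies(t)
    row = locus_stats(freqs, t, "L0")
    assert row.na == 1 and row.he == 0.0
    assert row.f is None and row.fnull is None
    assert row.hw == "ND"
    assert row.pid_unrelated == 1.0 and row.pid_sib == 1.0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def test_hw_biallelic_exact_sums_conditional_distribution():
    # all heterozygotes: strong excess -> small p
    t = make_table([[(100, 102)]] * 20)
    p_het = hw_exact_test(t, "L0")
    assert p_het < 0.01
    # HW-balanced table: p should not be extreme
    t2 = make_table([[(100, 100)]] * 5 + [[(100, 102)]] * 10 + [[(102, 102)]] * 5)
    assert hw_exact_test(t2, "L0") > 0.5


def test_hw_biallelic_matches_monte_carlo():
    rng = np.random.default_rng(7)
    t = random_table(rng, 30, 1, n_alleles=2)
    exact = hw_exact_test(t, "L0")
    # brute Monte Carlo on the same statistic
    from grapegen.diversity import _log_table_prob
    cells = [t.calls[i, 0] for i in range(30)]
    genes = [a for c in cells for a in c]
    ac = {a: genes.count(a) for a in set(genes)}
    gc = {}
    for c in cells:
        gc[c] = gc.get(c, 0) + 1
    obs = _log_table_prob(gc, ac, 30)
    hits = 0
    reps = 4000
    arr = np.array(genes, dtype=object)
    for _ in range(reps):
        rng.shuffle(arr)
        g2 = {}
        for k in range(30):
            pair = tuple(sorted((arr[2 * k], arr[2 * k + 1])))
            g2[pair] = g2.get(pair, 0) + 1
        if _log_table_prob(g2, ac, 30) <= obs + 1e-12:
            hits += 1
    mc = hits / reps
    assert exact == pytest.approx(mc, abs=0.03)


def test_hw_multiallelic_monte_carlo_seeded():
    rng = np.random.default_rng(11)
    t = random_table(rng, 40, 1, n_alleles=4)
    p1 = hw_exact_test(t, "L0", reps=2000, seed=5)
    p2 = hw_exact_test(t, "L0", reps=2000, seed=5)
    assert p1 == p2
    assert 0.0 < p1 <= 1.0
    with pytest.raises(ValueError):
        hw_exact_test(t, "L0", reps=100)


def test_hw_verdict_bands():
    assert hw_verdict(0.0005) == "***"
    assert hw_verdict(0.005) == "**"
    assert hw_verdict(0.03) == "*"
    assert hw_verdict(0.2) == "NS"


# ---------------------------------------------------------------------------
# cumulative identity and panel comparison
# ---------------------------------------------------------------------------

def test_cumulative_pid_is_product():
    vals = [0.1, 0.2, 0.5]
    assert cumulative_pid(vals) == pytest.approx(0.01)


def test_panel_equivalence_uses_most_informative_first():
    # with target 0.03: best two loci (0.1 * 0.2 = 0.02) suffice
    assert panel_equivalence([0.5, 0.1, 0.2], 0.03) == 2
    with pytest.raises(ValueError):
        panel_equivalence([0.5, 0.5], 1e-6)


def test_panel_summary_fields():
    t = make_table([[(100, 102), (104, 104)], [(100, 100), (104, 106)]])
    df = stats_table(t, hw_reps=1000)
    s = panel_summary(df)
    assert s["n_loci"] == 2
    assert s["A"] == 4
    assert s["mean_na"] == pytest.approx(2.0)
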