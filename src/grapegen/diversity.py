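"""Per-locus and panel-level diversity and identity statistics.

Implements the classical fingerprinting statistics for co-dominant marker
panels: allele frequencies, expected/observed heterozygosity, effective
allele number, rarefied allelic richness, fixation index, null-allele
frequency, polymorphic information content (PIC), and the probabilities of
identity for unrelated individuals and for full sibs, with cumulative
(multilocus) products and marker-panel comparison utilities.

Formulas (p_i are allele frequencies at a locus):

* He = 1 - sum p_i^2 (Nei gene diversity, uncorrected)
* Ne = 1 / sum p_i^2
* F  = 1 - Ho/He
* Fnull = (He - Ho) / (He + Ho)  (Chakraborty deficit ratio)
* PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
* P(ID)u   = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2
* P(ID)sib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4
* Nar(g) = sum_a [1 - C(G - c_a, g) / C(G, g)]   (rarefaction to g genes)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "AlleleFrequencyTable", "LocusStatsRow", "allele_frequencies",
    "locus_stats", "stats_table", "hw_exact_test", "cumulative_pid",
    "panel_equivalence", "panel_summary", "load_reference_stats",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-locus allele -> frequency maps with typed-sample counts."""

    freqs: dict[str, dict]        # locus -> {allele: frequency}
    n_typed: dict[str, int]       # locus -> diploid individuals typed
    counts: dict[str, dict]       # locus -> {allele: gene count}

    def gene_count(self, locus: str) -> int:
        return 2 * self.n_typed[locus]

    def loci(self) -> list[str]:
        return list(self.freqs)


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencyTable:
    """Tally allele frequencies per locus over typed individuals only."""
    if table.ploidy != 2:
        raise ValueError("allele frequencies are defined for diploid tables")
    freqs: dict[str, dict] = {}
    n_typed: dict[str, int] = {}
    counts: dict[str, dict] = {}
    for j, locus in enumerate(table.loci.names):
        tally: dict = {}
        n = 0
        for i in range(table.n_individuals):
            cell = table.calls[i, j]
            if cell is MISSING:
                continue
            n += 1
            for a in cell:
                tally[a] = tally.get(a, 0) + 1
        if n == 0:
            raise ValueError(f"locus {locus!r} has zero typed individuals")
        total = 2 * n
        counts[locus] = dict(sorted(tally.items()))
        freqs[locus] = {a: c / total for a, c in counts[locus].items()}
        n_typed[locus] = n
    return AlleleFrequencyTable(freqs, n_typed, counts)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

@dataclass
class LocusStatsRow:
    locus: str
    n: int
    md_pct: float
    na: int
    ne: float
    nar: float
    he: float
    ho: float
    f: Optional[float]
    hw: str
    fnull: Optional[float]
    pic: float
    pid_unrelated: float
    pid_sib: float
    maf: Optional[float] = None


def _identity_stats(p: np.ndarray) -> tuple[float, float, float, float]:
    """(He, PIC, PIDu, PIDsib) from an allele-frequency vector."""
    sp2 = float(np.sum(p ** 2))
    sp4 = float(np.sum(p ** 4))
    he = 1.0 - sp2
    # sum_{i<j} p_i^2 p_j^2 = ((sum p^2)^2 - sum p^4) / 2
    cross = (sp2 ** 2 - sp4) / 2.0
    pic = 1.0 - sp2 - 2.0 * cross
    pid_u = sp4 + 4.0 * cross
    pid_sib = 0.25 + 0.5 * sp2 + 0.5 * sp2 ** 2 - 0.25 * sp4
    return he, pic, pid_u, pid_sib


def _rarefied_richness(gene_counts: Sequence[int], g: int) -> float:
    """Expected allele count in a random draw of g genes (hypergeometric)."""
    total = int(sum(gene_counts))
    if g > total:
        raise ValueError(f"rarefaction size g={g} exceeds gene count {total}")
    log_denom = gammaln(total - g + 1) - gammaln(total + 1)
    out = 0.0
    for c in gene_counts:
        if total - c < g:
            out += 1.0
        else:
            log_num = gammaln(total - c + 1) - gammaln(total - c - g + 1)
            out += 1.0 - math.exp(log_num + log_denom)
    return out


def observed_heterozygosity(table: GenotypeTable, locus: str) -> float:
    j = table.locus_index(locus)
    het = n = 0
    for i in range(table.n_individuals):
        cell = table.calls[i, j]
        if cell is MISSING:
            continue
        n += 1
        het += cell[0] != cell[1]
    return het / n if n else float("nan")


def locus_stats(freqs: AlleleFrequencyTable, table: GenotypeTable, locus: str,
                g: Optional[int] = None, hw_reps: int = 10_000,
                hw_seed: int = 0) -> LocusStatsRow:
    """All per-locus diversity/identity statistics.

    ``g`` is the rarefaction gene-sample size; it defaults to twice the
    smallest number of typed individuals across loci (the smallest complete
    gene sample, so richness is comparable across loci).
    """
    p = np.array(list(freqs.freqs[locus].values()))
    counts = list(freqs.counts[locus].values())
    n = freqs.n_typed[locus]
    if g is None:
        g = 2 * min(freqs.n_typed.values())
    he, pic, pid_u, pid_sib = _identity_stats(p)
    ne = 1.0 / float(np.sum(p ** 2))
    ho = observed_heterozygosity(table, locus)
    na = len(p)
    monomorphic = na < 2
    if monomorphic:
        f = fnull = None
        hw = "ND"
        pid_u = pid_sib = 1.0
    else:
        f = 1.0 - ho / he
        fnull = (he - ho) / (he + ho)
        hw = hw_verdict(hw_exact_test(table, locus, reps=hw_reps, seed=hw_seed))
    md = 100.0 * (table.n_individuals - n) / table.n_individuals
    maf = float(p.min()) if na == 2 else None
    return LocusStatsRow(locus, n, md, na, ne, _rarefied_richness(counts, g),
                         he, ho, f, hw, fnull, pic, pid_u, pid_sib, maf)


def stats_table(table: GenotypeTable, g: Optional[int] = None,
                hw_reps: int = 10_000, hw_seed: int = 0) -> pd.DataFrame:
    """Per-locus statistics for every locus, as a DataFrame."""
    freqs = allele_frequencies(table)
    rows = [locus_stats(freqs, table, loc, g=g, hw_reps=hw_reps, hw_seed=hw_seed)
            for loc in table.loci.names]
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _log_table_prob(genotype_counts: dict, allele_counts: dict, n: int) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    lp = gammaln(n + 1) + h * math.log(2.0)
    lp -= sum(gammaln(c + 1) for c in genotype_counts.values())
    lp += sum(gammaln(c + 1) for c in allele_counts.values())
    lp -= gammaln(2 * n + 1)
    return lp


def hw_exact_test(table: GenotypeTable, locus: str, reps: int = 10_000,
                  seed: int = 0) -> float:
    """Exact test of departure from Hardy-Weinberg proportions.

    Biallelic loci are fully enumerated (exact conditional test); loci with
    more alleles use a seeded Monte Carlo permutation of gene copies. The
    p-value is the probability, under the conditional null, of a genotype
    table no more probable than the observed one.
    """
    j = table.locus_index(locus)
    cells = [table.calls[i, j] for i in range(table.n_individuals)
             if table.calls[i, j] is not MISSING]
    n = len(cells)
    genes = [a for c in cells for a in c]
    alleles = sorted(set(genes))
    if len(alleles) < 2:
        raise ValueError(f"locus {locus!r} is monomorphic: HW test not done")
    allele_counts = {a: genes.count(a) for a in alleles}

    geno_counts: dict = {}
    for c in cells:
        geno_counts[c] = geno_counts.get(c, 0) + 1
    obs_lp = _log_table_prob(geno_counts, allele_counts, n)

    if len(alleles) == 2:
        a, b = alleles
        ca = allele_counts[a]
        p_total = p_le = 0.0
        # heterozygote count shares parity with the minor allele count
        for nh in range(ca % 2, min(ca, 2 * n - ca) + 1, 2):
            naa = (ca - nh) // 2
            nbb = n - naa - nh
            if nbb < 0:
                continue
            gc = {(a, a): naa, tuple(sorted((a, b))): nh, (b, b): nbb}
            gc = {k: v for k, v in gc.items() if v > 0}
            lp = _log_table_prob(gc, allele_counts, n)
            pr = math.exp(lp)
            p_total += pr
            if lp <= obs_lp + 1e-12:
                p_le += pr
        return min(1.0, p_le / p_total)

    if reps < 1000:
        raise ValueError("Monte Carlo HW test needs reps >= 1000")
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes, dtype=object)
    hits = 0
    for _ in range(reps):
        rng.shuffle(gene_arr)
        gc: dict = {}
        for k in range(n):
            pair = tuple(sorted((gene_arr[2 * k], gene_arr[2 * k + 1])))
            gc[pair] = gc.get(pair, 0) + 1
        if _log_table_prob(gc, allele_counts, n) <= obs_lp + 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


def hw_verdict(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


# ---------------------------------------------------------------------------
# panel-level quantities
# ---------------------------------------------------------------------------

def cumulative_pid(pid_values: Sequence[float] | pd.Series,
                   loci_subset: Optional[Sequence[int]] = None) -> float:
    """Product of per-locus P(ID) values over a locus subset."""
    vals = np.asarray(pid_values, dtype=float)
    if loci_subset is not None:
        vals = vals[list(loci_subset)]
    if vals.size == 0:
        raise ValueError("empty locus subset")
    return float(np.prod(vals))


def panel_equivalence(pid_values: Sequence[float], target_cum_pid: float) -> int:
    """Smallest number of most-informative loci matching a target power.

    Loci are ranked by ascending per-locus P(ID) (most informative first)
    and their values multiplied until the running product is <= the target
    cumulative P(ID); returns that prefix length.
    """
    if target_cum_pid <= 0:
        raise ValueError("target must be positive")
    vals = np.sort(np.asarray(pid_values, dtype=float))
    prod = np.cumprod(vals)
    hit = np.nonzero(prod <= target_cum_pid)[0]
    if hit.size == 0:
        raise ValueError("panel insufficient: full product exceeds target")
    return int(hit[0]) + 1


def panel_summary(rows: pd.DataFrame) -> dict:
    """Unweighted panel means (Na, Ho, He, PIC) and total allele count A."""
    if len(rows) == 0:
        raise ValueError("empty stats table")
    return {
        "n_loci": int(len(rows)),
        "A": int(rows["na"].sum()),
        "mean_na": float(rows["na"].mean()),
        "mean_ho": float(rows["ho"].mean()),
        "mean_he": float(rows["he"].mean()),
        "mean_pic": float(rows["pic"].mean()),
    }


def load_reference_stats(panel: str) -> pd.DataFrame:
    """Published per-locus statistics for the 36-SSR / 45-SNP grape panels.

    ``panel`` is "ssr36" or "snp45". The SSR table includes a ``common9``
    flag marking the nine-locus core fingerprinting set.
    """
    fname = {"ssr36": "ssr36_reference_stats.csv",
             "snp45": "snp45_reference_stats.csv"}[panel]
    with resources.files("grapegen.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)
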