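"""Likelihood-based parentage analysis with a simulation-calibrated
critical LOD.

For each locus the likelihood of the observed offspring genotype is
computed under H1 (the candidate(s) are the parent(s); Mendelian
transmission) and H2 (the offspring is a random Hardy-Weinberg draw from
the population allele frequencies). Genotyping error is modelled as
independent replacement of each observed genotype by a random HW genotype
with probability epsilon, which keeps exclusions finite. With q = 1 - eps:

* duo:  L1 = q^2 T(o|p)  + (1 - q^2) HW(o)
* trio: L1 = q^3 T(o|m,f) + q^2 eps [T(o|m) + T(o|f)] + (q eps^2 + eps) HW(o)
* H2:   L2 = HW(o)

LOD = sum over co-typed loci of ln(L1/L2). The critical LOD for a given
confidence level is obtained by simulating offspring from the candidate
population (true parents present with the configured sampling proportion)
and choosing the most permissive threshold at which the assigned fraction
achieves that precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import numpy as np

from .diversity import AlleleFrequencyTable
from .genotypes import GenotypeTable

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_offspring: int = 1_000_000
    prop_sampled: float = 0.01
    selfing_allowed: bool = True
    relatives_present: bool = True
    error_rate: float = 0.01
    typed_rate: float = 1.0
    confidence_strict: float = 0.95
    confidence_relaxed: float = 0.80

    def __post_init__(self):
        for name in ("prop_sampled", "error_rate", "typed_rate",
                     "confidence_strict", "confidence_relaxed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0,1]")


@dataclass
class ParentageResult:
    offspring: str
    parents: tuple                      # (p1,) duo or (p1, p2) trio
    loci_compared: int
    mismatches: int
    lod: float
    confidence: str                     # "strict95" | "relaxed80" | "none"
    maternal: str = "undetermined"
    kind: str = "trio"                  # "trio" | "duo"


class ParentageEngine:
    """Vectorized per-locus likelihood computations on integer-coded genotypes."""

    def __init__(self, freqs: AlleleFrequencyTable, loci: Sequence[str],
                 eps: float = 0.01):
        if not 0.0 <= eps < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        self.loci = list(loci)
        self.eps = eps
        self.allele_index: list[dict] = []
        self.p: list[np.ndarray] = []
        self._floor: list[float] = []
        for locus in self.loci:
            fmap = freqs.freqs[locus]
            idx = {a: k for k, a in enumerate(fmap)}
            self.allele_index.append(idx)
            self.p.append(np.array(list(fmap.values()), dtype=float))
            self._floor.append(1.0 / (freqs.gene_count(locus) + 1))

    # -- coding ------------------------------------------------------------
    def code_table(self, table: GenotypeTable) -> np.ndarray:
        """(N, L, 2) integer codes; -1 for missing; unseen alleles floored."""
        n = table.n_individuals
        out = np.full((n, len(self.loci), 2), -1, dtype=np.int32)
        for j, locus in enumerate(self.loci):
            tj = table.locus_index(locus)
            idx = self.allele_index[j]
            for i in range(n):
                cell = table.calls[i, tj]
                if cell is None:
                    continue
                for c, a in enumerate(cell):
                    if a not in idx:
                        log.warning("allele %r at %s absent from frequency table; "
                                    "added at floor frequency", a, locus)
                        idx[a] = len(self.p[j])
                        self.p[j] = np.append(self.p[j], self._floor[j])
                    out[i, j, c] = idx[a]
        return out

    # -- per-locus primitives ------------------------------------------------
    @staticmethod
    def _transmit(par1, par2, allele):
        """P(parent transmits ``allele``), elementwise on coded arrays."""
        return 0.5 * ((par1 == allele).astype(float) + (par2 == allele).astype(float))

    def _hw(self, j, o1, o2):
        p = self.p[j]
        het = o1 != o2
        return np.where(het, 2.0 * p[o1] * p[o2], p[o1] ** 2)

    # -- duo ---------------------------------------------------------------
    def duo_lod_matrix(self, off: np.ndarray, cand: np.ndarray):
        """LOD, Mendelian mismatches and co-typed loci for every
        offspring x candidate combination.

        ``off`` is (n_off, L, 2), ``cand`` is (n_cand, L, 2). Returns three
        (n_off, n_cand) arrays.
        """
        q = 1.0 - self.eps
        n_off, n_cand = off.shape[0], cand.shape[0]
        lod = np.zeros((n_off, n_cand))
        mism = np.zeros((n_off, n_cand), dtype=int)
        compared = np.zeros((n_off, n_cand), dtype=int)
        for j in range(len(self.loci)):
            o1, o2 = off[:, j, 0][:, None], off[:, j, 1][:, None]
            c1, c2 = cand[:, j, 0][None, :], cand[:, j, 1][None, :]
            typed = (o1 >= 0) & (c1 >= 0)
            if not typed.any():
                continue
            o1s, o2s = np.maximum(o1, 0), np.maximum(o2, 0)
            c1s, c2s = np.maximum(c1, 0), np.maximum(c2, 0)
            p = self.p[j]
            t1 = self._transmit(c1s, c2s, o1s)
            t2 = self._transmit(c1s, c2s, o2s)
            het = o1s != o2s
            T2 = np.where(het, t1 * p[o2s] + t2 * p[o1s], t1 * p[o1s])
            hw = self._hw(j, o1s, o2s)
            L1 = q * q * T2 + (1.0 - q * q) * hw
            with np.errstate(divide="ignore"):
                contrib = np.log(L1) - np.log(hw)
            lod += np.where(typed, contrib, 0.0)
            mism += typed & (T2 == 0.0)
            compared += typed
        return lod, mism, compared

    # -- trio ---------------------------------------------------------------
    def trio_lod(self, off: np.ndarray, par1: np.ndarray, par2: np.ndarray):
        """Row-aligned trio LODs: all three arrays are (n, L, 2)."""
        q = 1.0 - self.eps
        n = off.shape[0]
        lod = np.zeros(n)
        mism = np.zeros(n, dtype=int)
        compared = np.zeros(n, dtype=int)
        for j in range(len(self.loci)):
            o1, o2 = off[:, j, 0], off[:, j, 1]
            m1, m2 = par1[:, j, 0], par1[:, j, 1]
            f1, f2 = par2[:, j, 0], par2[:, j, 1]
            typed = (o1 >= 0) & (m1 >= 0) & (f1 >= 0)
            if not typed.any():
                continue
            o1s, o2s = np.maximum(o1, 0), np.maximum(o2, 0)
            p = self.p[j]
            tm1 = self._transmit(np.maximum(m1, 0), np.maximum(m2, 0), o1s)
            tm2 = self._transmit(np.maximum(m1, 0), np.maximum(m2, 0), o2s)
            tf1 = self._transmit(np.maximum(f1, 0), np.maximum(f2, 0), o1s)
            tf2 = self._transmit(np.maximum(f1, 0), np.maximum(f2, 0), o2s)
            het = o1s != o2s
            T3 = np.where(het, tm1 * tf2 + tm2 * tf1, tm1 * tf1)
            T2m = np.where(het, tm1 * p[o2s] + tm2 * p[o1s], tm1 * p[o1s])
            T2f = np.where(het, tf1 * p[o2s] + tf2 * p[o1s], tf1 * p[o1s])
            hw = self._hw(j, o1s, o2s)
            L1 = q ** 3 * T3 + q * q * self.eps * (T2m + T2f) \
                + (q * self.eps ** 2 + self.eps) * hw
            with np.errstate(divide="ignore"):
                contrib = np.log(L1) - np.log(hw)
            lod += np.where(typed, contrib, 0.0)
            mism += typed & (T3 == 0.0)
            compared += typed
        return lod, mism, compared

    # -- HW sampling --------------------------------------------------------
    def random_genotypes(self, rng, n: int) -> np.ndarray:
        """n random Hardy-Weinberg multilocus genotypes, coded."""
        out = np.empty((n, len(self.loci), 2), dtype=np.int32)
        for j, p in enumerate(self.p):
            pn = p / p.sum()
            out[:, j, :] = rng.choice(len(pn), size=(n, 2), p=pn)
        out.sort(axis=2)
        return out


def transition_probability(engine: ParentageEngine, g_off: dict, g_par1: dict,
                           g_par2: Optional[dict] = None) -> tuple[float, int, int]:
    """(LOD, mismatches, loci_compared) for one duo or trio of genotype dicts."""

    def code_row(g):
        row = np.full((1, len(engine.loci), 2), -1, dtype=np.int32)
        for j, locus in enumerate(engine.loci):
            cell = g.get(locus)
            if cell is None:
                continue
            for c, a in enumerate(sorted(cell)):
                if a not in engine.allele_index[j]:
                    engine.allele_index[j][a] = len(engine.p[j])
                    engine.p[j] = np.append(engine.p[j], engine._floor[j])
                row[0, j, c] = engine.allele_index[j][a]
        return row

    off = code_row(g_off)
    p1 = code_row(g_par1)
    if g_par2 is None:
        lod, mism, comp = engine.duo_lod_matrix(off, p1)
        return float(lod[0, 0]), int(mism[0, 0]), int(comp[0, 0])
    p2 = code_row(g_par2)
    lod, mism, comp = engine.trio_lod(off, p1, p2)
    return float(lod[0]), int(mism[0]), int(comp[0])


# ---------------------------------------------------------------------------
# offspring simulation and critical LOD
# ---------------------------------------------------------------------------

def _mendelian_offspring(rng, par1: np.ndarray, par2: np.ndarray) -> np.ndarray:
    """One allele per parent per locus; parents are (n, L, 2) coded arrays."""
    n, L, _ = par1.shape
    pick1 = rng.integers(0, 2, size=(n, L))
    pick2 = rng.integers(0, 2, size=(n, L))
    off = np.stack([np.take_along_axis(par1, pick1[..., None], 2)[..., 0],
                    np.take_along_axis(par2, pick2[..., None], 2)[..., 0]], axis=2)
    off = off.astype(np.int32)
    off.sort(axis=2)
    return off


def _apply_errors(rng, engine: ParentageEngine, codes: np.ndarray, eps: float) -> np.ndarray:
    """Replace each genotype by a random HW draw with probability eps."""
    if eps <= 0:
        return codes
    out = codes.copy()
    n, L, _ = codes.shape
    err = rng.random((n, L)) < eps
    if err.any():
        repl = engine.random_genotypes(rng, n)
        out[err] = repl[err]
    out[codes[..., 0] < 0] = -1
    return out


def best_pairs(engine: ParentageEngine, off: np.ndarray, cand: np.ndarray,
               selfing: bool = True, top: int = 5, exclude=None):
    """Best candidate parent pair per offspring via a two-stage search.

    Stage 1 scores every single candidate (duo LOD); stage 2 evaluates all
    parent pairs among each offspring's ``top`` duo candidates. Returns
    (pair indices (n_off, 2), trio LOD, mismatches, loci compared) plus the
    duo stage results.
    """
    duo_lod, duo_mism, duo_comp = engine.duo_lod_matrix(off, cand)
    if exclude is not None:
        duo_lod = duo_lod.copy()
        for i, js in exclude.items():
            duo_lod[i, js] = -np.inf
    n_off, n_cand = duo_lod.shape
    k = min(top, n_cand)
    top_idx = np.argpartition(-duo_lod, k - 1, axis=1)[:, :k]

    best_lod = np.full(n_off, -np.inf)
    best_pair = np.zeros((n_off, 2), dtype=np.int64)
    best_mism = np.zeros(n_off, dtype=int)
    best_comp = np.zeros(n_off, dtype=int)
    pair_slots = [(a, b) for a, b in combinations_with_replacement(range(k), 2)
                  if selfing or a != b]
    for a, b in pair_slots:
        i1, i2 = top_idx[:, a], top_idx[:, b]
        lod, mism, comp = engine.trio_lod(off, cand[i1], cand[i2])
        better = lod > best_lod
        best_lod[better] = lod[better]
        best_pair[better, 0] = i1[better]
        best_pair[better, 1] = i2[better]
        best_mism[better] = mism[better]
        best_comp[better] = comp[better]
    return best_pair, best_lod, best_mism, best_comp, (duo_lod, duo_mism, duo_comp)


def _precision_threshold(lods: np.ndarray, correct: np.ndarray, level: float) -> float:
    """Most permissive LOD threshold achieving assignment precision >= level."""
    order = np.argsort(-lods)
    sorted_lods = lods[order]
    cum_correct = np.cumsum(correct[order])
    k = np.arange(1, len(lods) + 1)
    ok = cum_correct / k >= level
    if not ok.any():
        return float("inf")
    k_best = int(np.nonzero(ok)[0][-1])
    return float(sorted_lods[k_best])


def simulate_critical_lod(freqs: AlleleFrequencyTable, candidates: GenotypeTable,
                          cfg: SimulationConfig, seed: int = 0,
                          loci: Optional[Sequence[str]] = None) -> dict[str, float]:
    """Critical LOD per confidence level from offspring simulation.

    Offspring are generated from true parents that are, independently,
    present in the candidate set with probability ``cfg.prop_sampled`` (else
    drawn from the allele frequencies); observed genotypes carry the
    configured error and typing rates. For each offspring the best candidate
    parent pair is found and the threshold achieving the requested
    assignment precision is returned for the strict and relaxed levels.
    """
    loci = list(loci) if loci is not None else list(freqs.freqs)
    engine = ParentageEngine(freqs, loci, eps=cfg.error_rate)
    cand = engine.code_table(candidates)
    n_cand = cand.shape[0]
    if n_cand < 10:
        log.warning("only %d candidates: critical LOD will be unstable", n_cand)
    rng = np.random.default_rng(seed)
    n = cfg.n_offspring

    sampled1 = rng.random(n) < cfg.prop_sampled
    sampled2 = rng.random(n) < cfg.prop_sampled
    idx1 = rng.integers(0, n_cand, n)
    idx2 = rng.integers(0, n_cand, n)
    if not cfg.selfing_allowed:
        clash = sampled1 & sampled2 & (idx1 == idx2)
        idx2[clash] = (idx2[clash] + 1) % n_cand
    par1 = np.where(sampled1[:, None, None], cand[idx1],
                    engine.random_genotypes(rng, n))
    par2 = np.where(sampled2[:, None, None], cand[idx2],
                    engine.random_genotypes(rng, n))
    off = _mendelian_offspring(rng, par1, par2)
    off = _apply_errors(rng, engine, off, cfg.error_rate)
    if cfg.typed_rate < 1.0:
        untyped = rng.random((n, len(loci))) >= cfg.typed_rate
        off[untyped] = -1

    pair, lod, _, _, _ = best_pairs(engine, off, cand, selfing=cfg.selfing_allowed)
    both = sampled1 & sampled2
    correct = both & (
        ((pair[:, 0] == idx1) & (pair[:, 1] == idx2))
        | ((pair[:, 0] == idx2) & (pair[:, 1] == idx1)))
    finite = np.isfinite(lod)
    return {
        "strict95": _precision_threshold(lod[finite], correct[finite],
                                         cfg.confidence_strict),
        "relaxed80": _precision_threshold(lod[finite], correct[finite],
                                          cfg.confidence_relaxed),
    }


# ---------------------------------------------------------------------------
# assignment on real data
# ---------------------------------------------------------------------------

def flag_null_loci(stats_rows, threshold: float = 0.1) -> list[str]:
    """Loci whose null-allele frequency estimate exceeds ``threshold``.

    These inflate apparent homozygosity and fake Mendelian exclusions, so
    they are dropped from parentage panels.
    """
    out = []
    for _, row in stats_rows.iterrows():
        if row["fnull"] is not None and not (isinstance(row["fnull"], float) and math.isnan(row["fnull"])):
            if row["fnull"] > threshold:
                out.append(row["locus"])
    return out


def assign_parentage(offspring_table: GenotypeTable, candidates: GenotypeTable,
                     freqs: AlleleFrequencyTable, critical: dict[str, float] | float,
                     loci: Optional[Sequence[str]] = None, eps: float = 0.01,
                     max_mismatch_frac: float = 0.05, min_typed_loci: int = 10,
                     selfing: bool = True) -> list[ParentageResult]:
    """Trio-first parentage assignment against a candidate set.

    A trio is accepted when its LOD reaches the strict critical value and
    its Mendelian mismatches stay within floor(max_mismatch_frac * loci
    compared); offspring without an accepted trio fall back to single-parent
    (duo) assignment under the same rules. An offspring ID that also appears
    among the candidates is never proposed as its own parent.
    """
    loci = list(loci) if loci is not None else list(freqs.freqs)
    if isinstance(critical, (int, float)):
        critical = {"strict95": float(critical), "relaxed80": float(critical)}
    engine = ParentageEngine(freqs, loci, eps=eps)
    off = engine.code_table(offspring_table)
    cand = engine.code_table(candidates)
    typed_counts = (off[..., 0] >= 0).sum(axis=1)

    exclude: dict[int, list[int]] = {}
    for i, oid in enumerate(offspring_table.individuals):
        if oid in candidates.individuals:
            exclude[i] = [candidates.individuals.index(oid)]

    pair, lod, mism, comp, (duo_lod, duo_mism, duo_comp) = best_pairs(
        engine, off, cand, selfing=selfing, exclude=exclude)
    for i, js in exclude.items():
        duo_lod[i, js] = -np.inf

    results: list[ParentageResult] = []
    for i, oid in enumerate(offspring_table.individuals):
        if typed_counts[i] < min_typed_loci:
            log.warning("offspring %s typed at %d < %d loci: skipped",
                        oid, typed_counts[i], min_typed_loci)
            continue
        budget = math.floor(max_mismatch_frac * comp[i])
        if np.isfinite(lod[i]) and mism[i] <= budget:
            conf = ("strict95" if lod[i] >= critical["strict95"]
                    else "relaxed80" if lod[i] >= critical["relaxed80"] else "none")
            if conf != "none":
                p1, p2 = (candidates.individuals[pair[i, 0]],
                          candidates.individuals[pair[i, 1]])
                results.append(ParentageResult(oid, (p1, p2), int(comp[i]),
                                               int(mism[i]), float(lod[i]), conf))
                continue
        # duo fallback
        j = int(np.argmax(duo_lod[i]))
        dbudget = math.floor(max_mismatch_frac * duo_comp[i, j])
        if np.isfinite(duo_lod[i, j]) and duo_mism[i, j] <= dbudget:
            conf = ("strict95" if duo_lod[i, j] >= critical["strict95"]
                    else "relaxed80" if duo_lod[i, j] >= critical["relaxed80"]
                    else "none")
            if conf != "none":
                results.append(ParentageResult(
                    oid, (candidates.individuals[j],), int(duo_comp[i, j]),
                    int(duo_mism[i, j]), float(duo_lod[i, j]), conf, kind="duo"))
    return results


# ---------------------------------------------------------------------------
# half-kinship screen
# ---------------------------------------------------------------------------

@dataclass
class KinPair:
    id_a: str
    id_b: str
    loci_compared: int
    failing_loci: int
    lod: float


def halfkin_screen(table: GenotypeTable, freqs: AlleleFrequencyTable,
                   loci: Optional[Sequence[str]] = None, eps: float = 0.01,
                   max_fail_frac: float = 0.05) -> list[KinPair]:
    """Candidate first-degree pairs: sharing >= 1 allele at (almost) every locus.

    A pair passes when the number of co-typed loci at which the two
    genotypes share no allele is within floor(max_fail_frac * L), and the
    pair is typed at >= L - floor(max_fail_frac * L) loci. A single-parent
    LOD is attached; parent-offspring vs full-sib is left to the caller.
    """
    loci = list(loci) if loci is not None else list(freqs.freqs)
    L = len(loci)
    budget = math.floor(max_fail_frac * L)
    engine = ParentageEngine(freqs, loci, eps=eps)
    codes = engine.code_table(table)
    lod, mism, comp = engine.duo_lod_matrix(codes, codes)
    out: list[KinPair] = []
    for a in range(len(table.individuals)):
        for b in range(a + 1, len(table.individuals)):
            if comp[a, b] < L - budget:
                continue
            if mism[a, b] <= budget:
                out.append(KinPair(table.individuals[a], table.individuals[b],
                                   int(comp[a, b]), int(mism[a, b]),
                                   float(lod[a, b])))
    out.sort(key=lambda k: -k.lod)
    return out
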