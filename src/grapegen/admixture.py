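"""Bayesian admixture inference for co-dominant multilocus genotypes.

Model: each individual i has a membership vector Q_i on K ancestral
populations; each allele copy originates from population k with probability
Q_ik and is then drawn from that population's allele frequencies P_k. The
Gibbs sampler cycles: (1) allele-copy origins Z | Q, P; (2) allele
frequencies P from Dirichlet posteriors — either independent per population
or the correlated F-model, where P_k ~ Dirichlet(p_anc (1-F_k)/F_k) shrinks
population frequencies toward a shared ancestral vector with per-population
drift F_k; (3) Q_i ~ Dirichlet(alpha + origin counts); (4) Metropolis update
of the symmetric Dirichlet parameter alpha. The model log-probability is
estimated as mean(loglik) - var(loglik)/2 over post-burn-in sweeps, and the
number of populations is chosen by comparing those estimates across K and
by the second-difference (delta-K) statistic over replicate runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotypes import GenotypeTable

log = logging.getLogger(__name__)

ALPHA_MAX = 10.0
F_MIN, F_MAX = 1e-3, 0.5


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray                       # (N, K) posterior mean memberships
    P: list                             # per locus (K, A) posterior mean freqs
    lnPXK: float
    seed: int
    iters: int
    burnin: int
    alpha_trace: np.ndarray = field(repr=False, default=None)
    individuals: list[str] = field(default_factory=list)
    freq_model: str = "correlated"


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Sample along the last axis of a normalized probability array."""
    c = probs.cumsum(axis=-1)
    u = rng.random(probs.shape[:-1] + (1,)) * c[..., -1:]
    return (u > c).sum(axis=-1)


def _dirichlet_rows(rng, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws via gamma sampling (vectorized)."""
    g = rng.gamma(np.maximum(alpha, 1e-9))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def run_admixture(table: GenotypeTable, K: int, iters: int = 2000,
                  burnin: int = 2000, seed: int = 0,
                  freq_model: str = "correlated",
                  alpha0: float = 1.0) -> AdmixtureResult:
    """Run the admixture Gibbs sampler on a diploid genotype table."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if iters <= 0 or burnin < 0:
        raise ValueError("iters must be > burnin >= 0")
    if freq_model not in ("correlated", "independent"):
        raise ValueError(f"unknown freq_model {freq_model!r}")
    rng = np.random.default_rng(seed)
    codes, allele_lists = table.encode()
    N, L, _ = codes.shape
    n_alleles = [len(a) for a in allele_lists]
    typed = codes[..., 0] >= 0                       # (N, L)

    if K == 1:
        # closed form: Q is a column of ones; P is the posterior-mean frequency
        Q = np.ones((N, 1))
        P, ll = [], 0.0
        for l in range(L):
            cnt = np.bincount(codes[typed[:, l], l].ravel(), minlength=n_alleles[l])
            p = (cnt + 1.0) / (cnt.sum() + n_alleles[l])
            P.append(p[None, :])
            ll += float(np.log(p[codes[typed[:, l], l]]).sum())
        return AdmixtureResult(1, Q, P, ll, seed, iters, burnin,
                               np.array([]), list(table.individuals), freq_model)

    lam = 1.0
    Q = _dirichlet_rows(rng, np.full((N, K), alpha0))
    P = [_dirichlet_rows(rng, np.full((K, A), lam)) for A in n_alleles]
    p_anc = [np.full(A, 1.0 / A) for A in n_alleles]
    F = np.full(K, 0.05)
    alpha = alpha0

    Q_sum = np.zeros((N, K))
    P_sum = [np.zeros((K, A)) for A in n_alleles]
    logliks = []
    alpha_trace = np.empty(iters + burnin)

    for sweep in range(iters + burnin):
        m = np.zeros((N, K))                        # origin counts per individual
        counts = [np.zeros((K, A)) for A in n_alleles]
        loglik = 0.0
        for l in range(L):
            mask = typed[:, l]
            a = codes[mask, l]                      # (n, 2)
            lik = P[l][:, a]                        # (K, n, 2)
            w = Q[mask].T[:, :, None] * lik         # (K, n, 2)
            tot = w.sum(axis=0)
            loglik += float(np.log(tot).sum())
            z = _sample_categorical(rng, np.moveaxis(w / tot, 0, -1))  # (n, 2)
            zk = z.ravel()
            av = a.ravel()
            np.add.at(counts[l], (zk, av), 1.0)
            idx = np.repeat(np.nonzero(mask)[0], 2)
            np.add.at(m, (idx, zk), 1.0)
        logliks.append(loglik)

        # P | Z
        if freq_model == "independent":
            for l in range(L):
                P[l] = _dirichlet_rows(rng, lam + counts[l])
        else:
            for l in range(L):
                prior = p_anc[l][None, :] * ((1.0 - F[:, None]) / F[:, None])
                P[l] = _dirichlet_rows(rng, prior + counts[l])
            _update_fmodel_hypers(rng, P, p_anc, F, n_alleles)

        # Q | Z
        Q = _dirichlet_rows(rng, alpha + m)

        # alpha Metropolis (uniform prior on (0, ALPHA_MAX])
        prop = alpha + rng.normal(0.0, 0.05)
        if 0.0 < prop <= ALPHA_MAX:
            cur = _dirichlet_symmetric_loglik(Q, alpha, K)
            new = _dirichlet_symmetric_loglik(Q, prop, K)
            if math.log(rng.random() + 1e-300) < new - cur:
                alpha = prop
        alpha_trace[sweep] = alpha

        if sweep >= burnin:
            Q_sum += Q
            for l in range(L):
                P_sum[l] += P[l]

    post = np.array(logliks[burnin:])
    lnPXK = float(post.mean() - post.var() / 2.0)
    Q_mean = Q_sum / iters
    P_mean = [s / iters for s in P_sum]
    half = alpha_trace[burnin:]
    if len(half) > 20:
        a1, a2 = half[: len(half) // 2].mean(), half[len(half) // 2:].mean()
        if abs(a2 - a1) > 0.5:
            log.warning("alpha trace drifts (%.3f -> %.3f); consider longer runs", a1, a2)
    return AdmixtureResult(K, Q_mean, P_mean, lnPXK, seed, iters, burnin,
                           alpha_trace, list(table.individuals), freq_model)


def _dirichlet_symmetric_loglik(Q: np.ndarray, a: float, K: int) -> float:
    from scipy.special import gammaln
    n = Q.shape[0]
    return float(n * (gammaln(K * a) - K * gammaln(a))
                 + (a - 1.0) * np.log(np.maximum(Q, 1e-300)).sum())


def _update_fmodel_hypers(rng, P, p_anc, F, n_alleles) -> None:
    """Metropolis updates of the ancestral frequencies and drift parameters."""
    from scipy.special import gammaln

    K = F.shape[0]

    def logp_locus(l, pa, f):
        c = pa[None, :] * ((1.0 - f[:, None]) / f[:, None])
        return float((gammaln(c.sum(axis=1)).sum() - gammaln(c).sum()
                      + ((c - 1.0) * np.log(np.maximum(P[l], 1e-300))).sum()))

    # ancestral frequencies: Dirichlet random-walk proposal per locus
    for l in range(len(P)):
        conc = 200.0
        prop = rng.dirichlet(np.maximum(p_anc[l] * conc, 1e-2))
        prop = np.maximum(prop, 1e-6)
        prop /= prop.sum()
        cur_lp = logp_locus(l, p_anc[l], F)
        new_lp = logp_locus(l, prop, F)
        fwd = _dirichlet_logpdf(prop, np.maximum(p_anc[l] * conc, 1e-2))
        bwd = _dirichlet_logpdf(p_anc[l], np.maximum(prop * conc, 1e-2))
        if math.log(rng.random() + 1e-300) < new_lp - cur_lp + bwd - fwd:
            p_anc[l] = prop

    # drift parameters: log-odds random walk, uniform prior on (F_MIN, F_MAX)
    for k in range(K):
        cur = F[k]
        x = math.log(cur / (1.0 - cur)) + rng.normal(0.0, 0.2)
        prop = 1.0 / (1.0 + math.exp(-x))
        if not (F_MIN < prop < F_MAX):
            continue
        Fp = F.copy()
        Fp[k] = prop
        cur_lp = sum(logp_locus(l, p_anc[l], F) for l in range(len(P)))
        new_lp = sum(logp_locus(l, p_anc[l], Fp) for l in range(len(P)))
        # Jacobian of the logit transform
        jac = math.log(prop * (1 - prop)) - math.log(cur * (1 - cur))
        if math.log(rng.random() + 1e-300) < new_lp - cur_lp + jac:
            F[k] = prop


def _dirichlet_logpdf(x, a) -> float:
    from scipy.special import gammaln
    return float(gammaln(a.sum()) - gammaln(a).sum()
                 + ((a - 1.0) * np.log(np.maximum(x, 1e-300))).sum())


# ---------------------------------------------------------------------------
# model choice across K
# ---------------------------------------------------------------------------

def evanno(results: Sequence[AdmixtureResult]):
    """Second-difference (delta-K) table from replicate runs grouped by K.

    Needs >= 3 consecutive K values with >= 2 replicates each. Returns a
    DataFrame with mean/sd of the model log-probability and delta-K for
    interior K, plus the suggested K (argmax delta-K).
    """
    import pandas as pd

    byk: dict[int, list[float]] = {}
    for r in results:
        byk.setdefault(r.K, []).append(r.lnPXK)
    ks = sorted(byk)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(v) < 2 for v in byk.values()):
        raise ValueError("need >= 2 replicates per K")
    rows = []
    for k in ks:
        v = np.array(byk[k], dtype=float)
        rows.append({"K": k, "mean_lnPXK": v.mean(), "sd_lnPXK": v.std(ddof=1),
                     "n_reps": len(v)})
    df = pd.DataFrame(rows).set_index("K")
    dk = []
    for k in ks:
        if k == ks[0] or k == ks[-1] or df.loc[k, "sd_lnPXK"] == 0:
            dk.append(np.nan)
        else:
            second = abs(df.loc[k - 1, "mean_lnPXK"] - 2 * df.loc[k, "mean_lnPXK"]
                         + df.loc[k + 1, "mean_lnPXK"])
            dk.append(second / df.loc[k, "sd_lnPXK"])
    df["delta_K"] = dk
    df.attrs["suggested_K"] = int(df["delta_K"].idxmax()) if df["delta_K"].notna().any() else None
    return df


# ---------------------------------------------------------------------------
# replicate alignment (label switching)
# ---------------------------------------------------------------------------

def _similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pairwise matrix agreement G in [0, 1]."""
    return 1.0 - float(((a - b) ** 2).sum()) / (2.0 * a.shape[0])


def _best_permutation(ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Column permutation of q maximizing agreement with ref (optimal)."""
    gain = ref.T @ q                                  # (K, K)
    rows, cols = linear_sum_assignment(-gain)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return perm


def align_replicates(q_list: Sequence[np.ndarray], reps: int = 100,
                     seed: int = 0) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Align replicate Q matrices over column permutations.

    Greedy accumulation: replicates are visited in random order, each aligned
    to the running mean of those already aligned; ``reps`` random input
    orders are tried and the best by total pairwise G is kept. Returns
    (aligned list in input order, mean Q, mean pairwise G).
    """
    shapes = {q.shape for q in q_list}
    if len(shapes) != 1:
        raise ValueError("replicate Q matrices differ in shape")
    if len(q_list) == 1:
        return [q_list[0].copy()], q_list[0].copy(), 1.0
    rng = np.random.default_rng(seed)
    n_rep = len(q_list)

    def align_order(order):
        aligned = [None] * n_rep
        first = order[0]
        aligned[first] = q_list[first].copy()
        acc = aligned[first].copy()
        cnt = 1
        for idx in order[1:]:
            perm = _best_permutation(acc / cnt, q_list[idx])
            aligned[idx] = q_list[idx][:, perm]
            acc += aligned[idx]
            cnt += 1
        g = np.mean([_similarity(aligned[i], aligned[j])
                     for i in range(n_rep) for j in range(i + 1, n_rep)])
        return aligned, float(g)

    best_aligned, best_g = align_order(list(range(n_rep)))
    for _ in range(max(0, reps - 1)):
        order = rng.permutation(n_rep).tolist()
        aligned, g = align_order(order)
        if g > best_g:
            best_aligned, best_g = aligned, g
    mean_q = np.mean(best_aligned, axis=0)
    return best_aligned, mean_q, best_g


def assign_membership(Q: np.ndarray, threshold: float = 0.75,
                      labels: Optional[Sequence[str]] = None) -> list:
    """Assign each individual to its argmax population if Q >= threshold.

    The boundary is inclusive; below it the individual is "admixed".
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    K = Q.shape[1]
    labels = list(labels) if labels is not None else [f"pop{k + 1}" for k in range(K)]
    out = []
    for row in Q:
        k = int(np.argmax(row))
        out.append(labels[k] if row[k] >= threshold else "admixed")
    return out
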