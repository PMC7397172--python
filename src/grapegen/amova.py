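"""Analysis of molecular variance (AMOVA) on a pairwise distance matrix.

Partitions squared inter-individual distances into among-group and
within-group variance components; Phi_PT is the among-group share of total
molecular variance, tested by permuting group labels. Groups of size one
are excluded with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distance import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class AmovaResult:
    phi_pt: float
    sigma_among: float
    sigma_within: float
    p_value: float
    n_permutations: int
    seed: int
    groups: dict[str, list[str]] = field(default_factory=dict)
    pairwise_phi: Optional[dict] = None
    pairwise_p: Optional[dict] = None


def _phi_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(phi_pt, sigma_among, sigma_within) from squared distances + labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    group_sizes = []
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        ng = len(idx)
        group_sizes.append(ng)
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    g = len(group_sizes)
    df_among, df_within = g - 1, n - g
    sizes = np.array(group_sizes)
    n0 = (n - (sizes ** 2).sum() / n) / df_among
    sigma_w = ss_within / df_within
    sigma_a = (ss_among / df_among - sigma_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else 0.0
    return phi, sigma_a, sigma_w


def amova(dm: DistanceMatrix, groups: dict[str, Sequence[str]],
          n_perm: int = 999, seed: int = 0,
          pairwise: bool = True) -> AmovaResult:
    """AMOVA over predefined groups of the matrix's individuals.

    ``groups`` maps group name -> member IDs. The p-value is the fraction of
    permuted label assignments yielding Phi at least as large as observed,
    with the +1 correction.
    """
    clean: dict[str, list[str]] = {}
    for name, members in groups.items():
        members = [m for m in members if m in dm.ids]
        if len(members) < 2:
            log.warning("group %r has <2 members; excluded from AMOVA", name)
            continue
        clean[name] = list(members)
    if len(clean) < 2:
        raise ValueError("AMOVA needs >= 2 groups with >= 2 members")

    ids = [m for members in clean.values() for m in members]
    idx = [dm.ids.index(m) for m in ids]
    sub = dm.matrix[np.ix_(idx, idx)]
    if np.isnan(sub).any():
        raise ValueError("incomplete distance matrix over the grouped individuals")
    d2 = sub ** 2
    labels = np.concatenate([[gi] * len(members)
                             for gi, members in enumerate(clean.values())])

    phi, sa, sw = _phi_components(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        p_phi, _, _ = _phi_components(d2, perm)
        if p_phi >= phi - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    pw_phi = pw_p = None
    if pairwise and len(clean) > 2:
        pw_phi, pw_p = {}, {}
        names = list(clean)
        for a_i in range(len(names)):
            for b_i in range(a_i + 1, len(names)):
                a, b = names[a_i], names[b_i]
                r = amova(dm, {a: clean[a], b: clean[b]}, n_perm=n_perm,
                          seed=seed, pairwise=False)
                pw_phi[(a, b)] = r.phi_pt
                pw_p[(a, b)] = r.p_value
    return AmovaResult(phi, sa, sw, p, n_perm, seed, clean, pw_phi, pw_p)
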