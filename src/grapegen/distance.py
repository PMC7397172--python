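"""Proportion-of-shared-alleles distance and UPGMA clustering.

The pairwise dissimilarity between two multilocus genotypes is
d = -ln(PSA), where PSA is the proportion of shared alleles over co-typed
loci: shared alleles are counted by multiset intersection (a homozygote and
a heterozygote carrying one common allele share one allele, not two), and
the denominator is twice the number of co-typed loci. Missing loci are
dropped pairwise with a minimum-overlap guard. Trees are built by
average-linkage (UPGMA) agglomeration and exported as Newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray            # symmetric, NaN where unavailable
    overlap: np.ndarray           # co-typed locus counts per pair
    capped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not np.isnan(self.matrix).any()

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def psa_distance(table: GenotypeTable, loci: Optional[Sequence[str]] = None,
                 min_overlap: Optional[int] = None) -> DistanceMatrix:
    """Pairwise -ln(proportion of shared alleles) distance matrix.

    Pairs with fewer than ``min_overlap`` co-typed loci (default ceil(L/2))
    get a NaN cell. A pair sharing no alleles at all would have infinite
    distance; it is instead capped at -ln(1/(4L)) and flagged, keeping the
    matrix usable by UPGMA.
    """
    locs = list(loci) if loci is not None else table.loci.names
    L = len(locs)
    if min_overlap is None:
        min_overlap = math.ceil(L / 2)
    jj = [table.locus_index(x) for x in locs]
    n = table.n_individuals
    dm = np.zeros((n, n))
    ov = np.zeros((n, n), dtype=int)
    cap = -math.log(1.0 / (4 * L))
    capped = []
    for a in range(n):
        ov[a, a] = L
        for b in range(a + 1, n):
            shared = 0
            co = 0
            for j in jj:
                ga, gb = table.calls[a, j], table.calls[b, j]
                if ga is MISSING or gb is MISSING:
                    continue
                co += 1
                rest = list(gb)
                for x in ga:
                    if x in rest:
                        rest.remove(x)
                        shared += 1
            ov[a, b] = ov[b, a] = co
            if co < min_overlap:
                d = np.nan
            else:
                psa = shared / (2 * co)
                if psa == 0.0:
                    d = cap
                    capped.append((table.individuals[a], table.individuals[b]))
                else:
                    d = -math.log(psa)
            dm[a, b] = dm[b, a] = d
    return DistanceMatrix(list(table.individuals), dm, ov, capped)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    height: float
    name: Optional[str] = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]

    def leaf_depths(self, base: float = None) -> dict[str, float]:
        """Root-to-leaf path lengths (for ultrametricity checks)."""
        root_h = self.height if base is None else base
        if self.is_leaf:
            return {self.name: root_h - self.height}
        out = {}
        for c in self.children:
            out.update(c.leaf_depths(root_h))
        return out


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative clustering with node heights.

    Merge height is half the average between-cluster distance. Ties are
    broken deterministically on the smallest (row, col) index pair of the
    current cluster list, which is kept sorted by the minimum original
    leaf index of each cluster.
    """
    if not dm.complete:
        raise ValueError("incomplete distance matrix: UPGMA needs every pair")
    n = len(dm.ids)
    nodes: list[TreeNode] = [TreeNode(0.0, name=i) for i in dm.ids]
    sizes = [1] * n
    d = dm.matrix.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                val = d[active[ai], active[bi]]
                if best is None or val < best[0] - 1e-15:
                    best = (val, ai, bi)
        val, ai, bi = best
        a, b = active[ai], active[bi]
        new = TreeNode(val / 2.0, children=[nodes[a], nodes[b]])
        # average-linkage update, weighted by cluster sizes
        for ci in range(len(active)):
            c = active[ci]
            if c in (a, b):
                continue
            d[a, c] = d[c, a] = (sizes[a] * d[a, c] + sizes[b] * d[b, c]) / (sizes[a] + sizes[b])
        nodes[a] = new
        sizes[a] += sizes[b]
        active.pop(bi)
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Newick text with branch lengths as height differences."""

    def render(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        bls = f":{bl:.{precision}g}"
        if node.is_leaf:
            return f"{_quote(node.name)}{bls}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}){bls}"

    if tree.is_leaf:
        return f"{_quote(tree.name)};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    import pandas as pd
    pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids).to_csv(path)
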