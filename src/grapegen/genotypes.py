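"""Genotype tables and accession metadata.

A :class:`GenotypeTable` is an individuals x loci matrix of unordered
allele pairs (diploid nuclear markers) or single alleles (haploid cpSSR).
Missing data is whole-cell: a cell either carries a complete genotype or
nothing. Allele codes are integers (bp) for SSR/cpSSR and single
characters for SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .markers import MarkerDef, MarkerPanel

#: sentinel for a missing cell
MISSING = None


class Region(str, Enum):
    DALMATIA = "Dalmatia"
    ISTRIA_LITTORAL = "Istria-Littoral"
    NW_CROATIA = "NW-Croatia"
    SLAVONIA_DANUBE = "Slavonia-Danube"
    FOREIGN = "foreign"
    UNKNOWN = "unknown"


class AccessionStatus(str, Enum):
    """Nine curation status classes assigned by identity analysis."""

    UNIQUE = "I"
    SYNONYM_INTERNAL = "II"
    SYNONYM_NEIGHBOR = "III"
    SYNONYM_DISTANT = "IV"
    KNOWN_FOREIGN = "V"
    INTRUDER = "VI"
    QUESTIONABLE = "VII"
    MISLABELED = "VIII"
    SAMPLING_ERROR = "IX"
    UNRESOLVED = "unresolved"


@dataclass
class AccessionMeta:
    id: str
    declared_name: str = ""
    collection: str = ""
    region: Region = Region.UNKNOWN
    status: Optional[AccessionStatus] = None
    true_to_type: bool = False
    chlorotype: Optional[str] = None
    #: curation flags: subset of {"intruder", "mislabeled", "sampling_error"}
    flags: set = field(default_factory=set)


def _normalize_call(call, ploidy: int):
    """Sort an allele pair ascending; validate shape against ploidy."""
    if call is MISSING:
        return MISSING
    if ploidy == 1:
        if isinstance(call, (tuple, list)):
            if len(call) != 1:
                raise ValueError(f"haploid cell must hold one allele, got {call!r}")
            return (call[0],)
        return (call,)
    if not isinstance(call, (tuple, list)) or len(call) != 2:
        raise ValueError(f"diploid cell must hold two alleles, got {call!r}")
    a, b = call
    if a is None or b is None:
        raise ValueError(f"half-typed cell {call!r}: missing data must be whole-cell")
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeTable:
    individuals: list[str]
    loci: MarkerPanel
    calls: np.ndarray = field(repr=False)  # (N, L) object array of tuples / None
    ploidy: int = 2

    def __init__(self, individuals: Sequence[str], loci: MarkerPanel | Sequence[MarkerDef],
                 calls, ploidy: int = 2):
        self.individuals = list(individuals)
        self.loci = loci if isinstance(loci, MarkerPanel) else MarkerPanel(list(loci))
        self.ploidy = ploidy
        n, l = len(self.individuals), len(self.loci)
        arr = np.empty((n, l), dtype=object)
        for i in range(n):
            for j in range(l):
                cell = calls[i, j] if isinstance(calls, np.ndarray) else calls[i][j]
                arr[i, j] = _normalize_call(cell, ploidy)
        self.calls = arr
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate accession IDs")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def ind_index(self, ind: str) -> int:
        return self.individuals.index(ind)

    def locus_index(self, locus: str) -> int:
        return self.loci.names.index(locus)

    def get(self, ind: str, locus: str):
        return self.calls[self.ind_index(ind), self.locus_index(locus)]

    def genotype_row(self, ind: str) -> dict:
        i = self.ind_index(ind)
        return {name: self.calls[i, j] for j, name in enumerate(self.loci.names)}

    def subset(self, individuals: Optional[Iterable[str]] = None,
               loci: Optional[Iterable[str]] = None) -> "GenotypeTable":
        inds = list(individuals) if individuals is not None else self.individuals
        locs = list(loci) if loci is not None else self.loci.names
        ii = [self.ind_index(x) for x in inds]
        jj = [self.locus_index(x) for x in locs]
        return GenotypeTable(inds, self.loci.subset(locs),
                             self.calls[np.ix_(ii, jj)], self.ploidy)

    # -- missingness ------------------------------------------------------
    def typed_mask(self) -> np.ndarray:
        """Boolean (N, L) mask of typed (non-missing) cells."""
        return np.vectorize(lambda c: c is not MISSING, otypes=[bool])(self.calls)

    def missing_per_locus(self) -> dict[str, int]:
        mask = self.typed_mask()
        return {name: int((~mask[:, j]).sum()) for j, name in enumerate(self.loci.names)}

    # -- integer encoding (for numeric algorithms) ------------------------
    def encode(self, loci: Optional[Sequence[str]] = None):
        """Integer-code alleles per locus.

        Returns (codes, allele_lists): codes is (N, L, ploidy) int array with
        -1 for missing; allele_lists[j] maps code -> allele for locus j.
        """
        locs = list(loci) if loci is not None else self.loci.names
        jj = [self.locus_index(x) for x in locs]
        n = self.n_individuals
        codes = np.full((n, len(jj), self.ploidy), -1, dtype=np.int64)
        allele_lists: list[list] = []
        for out_j, j in enumerate(jj):
            alleles = sorted({a for i in range(n) if self.calls[i, j] is not MISSING
                              for a in self.calls[i, j]})
            lookup = {a: k for k, a in enumerate(alleles)}
            allele_lists.append(alleles)
            for i in range(n):
                cell = self.calls[i, j]
                if cell is not MISSING:
                    for p, a in enumerate(cell):
                        codes[i, out_j, p] = lookup[a]
        return codes, allele_lists

    def equals(self, other: "GenotypeTable") -> bool:
        return (self.individuals == other.individuals
                and self.loci.names == other.loci.names
                and self.ploidy == other.ploidy
                and all(self.calls[i, j] == other.calls[i, j]
                        for i in range(self.n_individuals)
                        for j in range(self.n_loci)))
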