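"""Marker definitions and panels.

Loci are organized into four categories by purpose: cat1 is the core
fingerprinting set (nine SSRs recommended for cultivar identification),
cat1+cat2 serve diversity, structure and parentage analyses, cat3 adds
support loci for structure, and cat4 holds the chloroplast microsatellites
used for chlorotype determination.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence


class MarkerSystem(str, Enum):
    SSR = "SSR"
    SNP = "SNP"
    CPSSR = "cpSSR"


class Category(str, Enum):
    CAT1 = "cat1"
    CAT2 = "cat2"
    CAT3 = "cat3"
    CAT4 = "cat4"


SNP_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class MarkerDef:
    """A single marker locus.

    SSR alleles are integer fragment lengths in bp; SNP alleles are
    nucleotide letters; cpSSR loci are haploid chloroplast microsatellites.
    """

    name: str
    system: MarkerSystem = MarkerSystem.SSR
    motif_length: Optional[int] = None
    category: Category = Category.CAT1
    expected_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.system == MarkerSystem.SSR and self.motif_length is not None:
            if self.motif_length < 1:
                raise ValueError(f"{self.name}: motif_length must be >= 1")
        if self.category == Category.CAT4 and self.system != MarkerSystem.CPSSR:
            raise ValueError(f"{self.name}: cat4 loci must be cpSSR")

    @property
    def ploidy(self) -> int:
        return 1 if self.system == MarkerSystem.CPSSR else 2


@dataclass
class MarkerPanel:
    """An ordered collection of marker loci with unique names."""

    loci: list[MarkerDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.loci]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate locus names in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> MarkerDef:
        for m in self.loci:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.loci]

    def subset(self, names: Iterable[str]) -> "MarkerPanel":
        wanted = list(names)
        return MarkerPanel([self[n] for n in wanted])

    def by_category(self, *cats: Category | str) -> "MarkerPanel":
        cset = {Category(c) for c in cats}
        return MarkerPanel([m for m in self.loci if m.category in cset])

    def by_system(self, system: MarkerSystem | str) -> "MarkerPanel":
        s = MarkerSystem(system)
        return MarkerPanel([m for m in self.loci if m.system == s])


def read_panel_csv(path: str | Path) -> MarkerPanel:
    """Read a panel definition CSV: name, system, motif_length, category[, min, max]."""
    loci = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rng = None
            if row.get("min") and row.get("max"):
                rng = (int(row["min"]), int(row["max"]))
            motif = row.get("motif_length") or None
            loci.append(
                MarkerDef(
                    name=row["name"],
                    system=MarkerSystem(row["system"]),
                    motif_length=int(motif) if motif else None,
                    category=Category(row["category"]),
                    expected_range=rng,
                )
            )
    return MarkerPanel(loci)


def write_panel_csv(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "system", "motif_length", "category", "min", "max"])
        for m in panel:
            lo, hi = m.expected_range if m.expected_range else ("", "")
            w.writerow([m.name, m.system.value, m.motif_length or "", m.category.value, lo, hi])
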