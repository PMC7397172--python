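"""Chloroplast SSR haplotypes: chlorotype assignment, regional frequencies,
and maternity designation within accepted parent pairs.

Chloroplast DNA is maternally inherited in grapevine, so the combination of
fragment lengths at four cpSSR loci defines a haplotype letter (the
chlorotype) that an offspring shares with its seed parent. When the two
parents of an accepted trio carry different chlorotypes, the parent whose
chlorotype matches the offspring is the mother.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .genotypes import MISSING, GenotypeTable

#: the chlorotype alphabet observed in European grapevine germplasm
CHLOROTYPE_LETTERS = tuple("ABCDEFGH")

NOT_DETERMINED = "n.d."


@dataclass
class ChlorotypeMap:
    """Lookup from a cpSSR fragment-length combination to a haplotype letter."""

    loci: list[str]                       # ordered cpSSR locus names
    rows: dict[tuple, str]                # length combination -> letter

    def __post_init__(self):
        if len(set(self.rows.values())) > len(CHLOROTYPE_LETTERS):
            raise ValueError("too many chlorotype letters")
        for letter in self.rows.values():
            if letter not in CHLOROTYPE_LETTERS:
                raise ValueError(f"chlorotype letter {letter!r} outside A-H")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChlorotypeMap":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            loci = header[:-1]
            rows: dict[tuple, str] = {}
            for rec in reader:
                combo = tuple(int(x) for x in rec[:-1])
                if combo in rows:
                    raise ValueError(f"duplicate combination {combo} in map")
                rows[combo] = rec[-1]
        return cls(loci, rows)

    @classmethod
    def default(cls) -> "ChlorotypeMap":
        """Literature-derived default map shipped with the package."""
        with resources.files("grapegen.data").joinpath(
                "chlorotype_map_default.csv").open() as fh:
            reader = csv.reader(fh)
            header = next(reader)
            loci = header[:-1]
            rows = {tuple(int(x) for x in rec[:-1]): rec[-1] for rec in reader}
        return cls(loci, rows)


def assign_chlorotype(cp_table: GenotypeTable, cmap: ChlorotypeMap) -> dict[str, str]:
    """Exact-match lookup of each accession's cpSSR length combination.

    Any missing cp locus or unmatched combination yields "n.d." — maternity
    is never inferred through incomplete haplotypes.
    """
    jj = [cp_table.locus_index(l) for l in cmap.loci]
    out: dict[str, str] = {}
    for i, ind in enumerate(cp_table.individuals):
        vals = []
        for j in jj:
            cell = cp_table.calls[i, j]
            if cell is MISSING:
                vals = None
                break
            vals.append(cell[0])
        if vals is None:
            out[ind] = NOT_DETERMINED
        else:
            out[ind] = cmap.rows.get(tuple(vals), NOT_DETERMINED)
    return out


def chlorotype_frequencies(assignments: dict[str, str],
                           regions: Optional[dict[str, str]] = None):
    """Counts and proportions of chlorotypes per region.

    "n.d." accessions are excluded from denominators; accessions without a
    region are grouped under "unknown".
    """
    import pandas as pd

    regions = regions or {}
    records = []
    for acc, letter in assignments.items():
        if letter == NOT_DETERMINED:
            continue
        records.append({"region": regions.get(acc, "unknown"), "chlorotype": letter})
    if not records:
        return pd.DataFrame(columns=["region", "chlorotype", "count", "proportion"])
    df = pd.DataFrame(records)
    counts = df.groupby(["region", "chlorotype"]).size().rename("count").reset_index()
    totals = counts.groupby("region")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def designate_mother(trio: tuple[str, str, str],
                     assignments: dict[str, str]) -> str:
    """Maternal designation for an accepted trio (offspring, parent1, parent2).

    Returns the maternal parent's ID when the parents' chlorotypes differ
    and the offspring matches exactly one of them; "undetermined" when the
    parents share a chlorotype or any member is "n.d."; "conflict" when the
    offspring matches neither parent (impossible under maternal inheritance).
    """
    off, p1, p2 = trio
    c_off = assignments.get(off, NOT_DETERMINED)
    c1 = assignments.get(p1, NOT_DETERMINED)
    c2 = assignments.get(p2, NOT_DETERMINED)
    if NOT_DETERMINED in (c_off, c1, c2):
        return "undetermined"
    if c1 == c2:
        return "undetermined"
    if c_off == c1:
        return p1
    if c_off == c2:
        return p2
    return "conflict"
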