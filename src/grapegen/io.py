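"""Readers/writers for genotype tables plus allele harmonization and binning.

CSV dialect: one row per accession (column ``id``), two columns per nuclear
locus named ``<locus>_1``/``<locus>_2`` (one column named ``<locus>`` for
cpSSR). Empty cells, ``NA`` and ``0`` denote missing data; missingness is
whole-cell, so a half-typed cell is rejected rather than guessed.
Interchange with admixture tooling uses the classic two-rows-per-individual
integer format with -9 for missing.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable
from .markers import MarkerPanel, MarkerSystem

log = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "0", "na", "n/a", "N/A"}


def _parse_allele(token: str, system: MarkerSystem):
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING
    if system == MarkerSystem.SNP:
        if token not in "ACGT":
            raise ValueError(f"invalid SNP allele {token!r}")
        return token
    return int(token)


def read_genotype_csv(path: str | Path | _io.TextIOBase, panel: MarkerPanel) -> GenotypeTable:
    """Read a genotype CSV for the loci in ``panel``.

    Raises ValueError (with row and locus named) on half-typed cells; alleles
    outside a locus's expected range are kept but warned about.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, newline="")
        close = True
    else:
        fh = path
    try:
        reader = csv.DictReader(fh)
        ploidy = 1 if all(m.system == MarkerSystem.CPSSR for m in panel) else 2
        individuals, rows = [], []
        for row in reader:
            ind = row["id"]
            individuals.append(ind)
            calls = []
            for m in panel:
                if m.ploidy == 1:
                    a = _parse_allele(row.get(m.name, ""), m.system)
                    calls.append(MISSING if a is MISSING else (a,))
                    continue
                a = _parse_allele(row.get(f"{m.name}_1", ""), m.system)
                b = _parse_allele(row.get(f"{m.name}_2", ""), m.system)
                if (a is MISSING) != (b is MISSING):
                    raise ValueError(
                        f"half-typed cell at accession {ind!r}, locus {m.name!r}")
                if a is MISSING:
                    calls.append(MISSING)
                else:
                    if m.expected_range and m.system != MarkerSystem.SNP:
                        lo, hi = m.expected_range
                        for x in (a, b):
                            if not lo <= x <= hi:
                                warnings.warn(
                                    f"allele {x} at {m.name} outside expected "
                                    f"range [{lo},{hi}] (accession {ind}); retained")
                    calls.append((a, b))
            rows.append(calls)
    finally:
        if close:
            fh.close()
    table = GenotypeTable(individuals, panel, rows, ploidy=ploidy)
    for locus, n_miss in table.missing_per_locus().items():
        if n_miss:
            log.info("locus %s: %d missing cells", locus, n_miss)
    return table


def write_genotype_csv(table: GenotypeTable, path: str | Path | _io.TextIOBase) -> None:
    """Write a table in the CSV dialect read by :func:`read_genotype_csv`.

    Homozygotes are written with both columns filled ("a","a") so diploid
    cells are never confusable with haploid cpSSR columns.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w", newline="")
        close = True
    else:
        fh = path
    try:
        w = csv.writer(fh)
        header = ["id"]
        for m in table.loci:
            header += [m.name] if m.ploidy == 1 else [f"{m.name}_1", f"{m.name}_2"]
        w.writerow(header)
        for i, ind in enumerate(table.individuals):
            row = [ind]
            for j, m in enumerate(table.loci):
                cell = table.calls[i, j]
                width = 1 if m.ploidy == 1 else 2
                row += [""] * width if cell is MISSING else [str(a) for a in cell]
            w.writerow(row)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# admixture-tool interchange format
# ---------------------------------------------------------------------------

def write_structure_format(table: GenotypeTable) -> str:
    """Two rows per individual, integer-recoded alleles, -9 = missing."""
    if table.ploidy != 2:
        raise ValueError("interchange format requires a nuclear diploid table")
    codes, _ = table.encode()
    lines = [" ".join(["id"] + table.loci.names)]
    for i, ind in enumerate(table.individuals):
        for p in range(2):
            vals = [str(codes[i, j, p] + 1) if codes[i, j, p] >= 0 else "-9"
                    for j in range(table.n_loci)]
            lines.append(" ".join([ind] + vals))
    return "\n".join(lines) + "\n"


def read_structure_format(text: str, panel: MarkerPanel,
                          allele_lists: Sequence[Sequence]) -> GenotypeTable:
    """Decode :func:`write_structure_format` output given the per-locus allele lists."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    body = lines[1:]
    if len(body) % 2:
        raise ValueError("expected two rows per individual")
    individuals, rows = [], []
    for k in range(0, len(body), 2):
        f1, f2 = body[k].split(), body[k + 1].split()
        if f1[0] != f2[0]:
            raise ValueError(f"row pairing broken at {f1[0]!r}/{f2[0]!r}")
        individuals.append(f1[0])
        calls = []
        for j in range(len(panel)):
            c1, c2 = int(f1[j + 1]), int(f2[j + 1])
            if (c1 == -9) != (c2 == -9):
                raise ValueError("half-typed cell in interchange text")
            calls.append(MISSING if c1 == -9
                         else (allele_lists[j][c1 - 1], allele_lists[j][c2 - 1]))
        rows.append(calls)
    return GenotypeTable(individuals, panel, rows, ploidy=2)


# ---------------------------------------------------------------------------
# allele-length harmonization against reference profiles
# ---------------------------------------------------------------------------

@dataclass
class OffsetReport:
    locus: str
    offset: int
    agreement: float
    n_comparisons: int
    inconsistent: bool


def harmonize_alleles(table: GenotypeTable, reference: GenotypeTable,
                      shared_ids: Sequence[tuple[str, str]] | Sequence[str],
                      min_agreement: float = 0.8,
                      ) -> tuple[GenotypeTable, list[OffsetReport]]:
    """Shift each locus's allele lengths onto a reference scale.

    Sizing offsets between runs (e.g. tailed-primer extension) are constant
    per locus, so the offset is estimated as the mode of (observed -
    reference) differences over shared accessions' sorted allele pairs and
    subtracted everywhere. The mode (not the mean) is used so a single
    mistyped reference cannot shift a locus. If fewer than ``min_agreement``
    of comparisons match the mode, the locus is flagged inconsistent and
    left unshifted.
    """
    pairs = [(s, s) if isinstance(s, str) else tuple(s) for s in shared_ids]
    reports: list[OffsetReport] = []
    new_calls = table.calls.copy()
    for j, m in enumerate(table.loci):
        diffs: list[int] = []
        jr = reference.locus_index(m.name)
        for obs_id, ref_id in pairs:
            obs = table.calls[table.ind_index(obs_id), j]
            ref = reference.calls[reference.ind_index(ref_id), jr]
            if obs is MISSING or ref is MISSING:
                continue
            diffs.extend(o - r for o, r in zip(obs, ref))
        if len(diffs) < 2:
            reports.append(OffsetReport(m.name, 0, 0.0, len(diffs), True))
            continue
        mode, count = Counter(diffs).most_common(1)[0]
        agreement = count / len(diffs)
        inconsistent = agreement < min_agreement
        offset = 0 if inconsistent else -mode
        reports.append(OffsetReport(m.name, offset, agreement, len(diffs), inconsistent))
        if offset:
            for i in range(table.n_individuals):
                cell = new_calls[i, j]
                if cell is not MISSING:
                    new_calls[i, j] = tuple(a + offset for a in cell)
    out = GenotypeTable(table.individuals, table.loci, new_calls, table.ploidy)
    return out, reports


# ---------------------------------------------------------------------------
# allele binning into size classes
# ---------------------------------------------------------------------------

def bin_alleles(table: GenotypeTable, locus: str,
                class_spacing: Optional[int] = None) -> GenotypeTable:
    """Cluster a locus's allele sizes into classes and snap to modal sizes.

    Single-linkage clustering with gap < ``class_spacing`` (default: the
    locus motif length); each cluster's members are replaced by its modal
    size (tie -> smallest). Off-ladder singletons sit in their own cluster
    and are preserved unchanged, so genuine one-bp variants survive.
    """
    j = table.locus_index(locus)
    m = table.loci[locus]
    spacing = class_spacing if class_spacing is not None else (m.motif_length or 1)
    if spacing not in (1, 2, 3):
        raise ValueError("class_spacing must be 1, 2 or 3")
    sizes = [a for i in range(table.n_individuals)
             if table.calls[i, j] is not MISSING for a in table.calls[i, j]]
    if not sizes:
        return table
    counts = Counter(sizes)
    uniq = sorted(counts)
    # single-linkage chains: break where the gap reaches the spacing
    clusters: list[list[int]] = [[uniq[0]]]
    for a in uniq[1:]:
        if a - clusters[-1][-1] < spacing:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    remap: dict[int, int] = {}
    for cl in clusters:
        best = min(cl, key=lambda a: (-counts[a], a))  # modal size, tie -> smallest
        for a in cl:
            remap[a] = best
    new_calls = table.calls.copy()
    for i in range(table.n_individuals):
        cell = new_calls[i, j]
        if cell is not MISSING:
            new_calls[i, j] = tuple(sorted(remap[a] for a in cell))
    return GenotypeTable(table.individuals, table.loci, new_calls, table.ploidy)
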