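"""Duplicate/synonym detection and accession status assignment.

Two accessions are duplicates of one another when their SSR profiles are
identical up to a small allele tolerance (default two alleles over the
fingerprinting panel), which absorbs genotyping errors and spontaneous
somatic mutations in clonally propagated material. Identity groups are the
transitive closure of the pairwise relation; a non-redundant set keeps one
representative per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genotypes import MISSING, AccessionMeta, AccessionStatus, GenotypeTable

#: countries considered neighbors when classifying external synonyms
NEIGHBOR_COUNTRIES = frozenset({
    "Slovenia", "Italy", "Hungary", "Serbia", "Bosnia-Herzegovina",
    "Montenegro", "Austria", "North Macedonia",
})


def pairwise_mismatch(g1: dict, g2: dict, loci: Sequence[str]) -> tuple[int, int]:
    """Count allele mismatches between two genotype dicts over ``loci``.

    Per co-typed locus the mismatch count is 2 minus the size of the
    multiset intersection of the two allele pairs, so tolerance is counted
    in alleles rather than loci. Returns (loci_compared, allele_mismatches).
    """
    compared = mism = 0
    for locus in loci:
        a, b = g1.get(locus), g2.get(locus)
        if a is MISSING or b is MISSING or a is None or b is None:
            continue
        compared += 1
        rest = list(b)
        shared = 0
        for x in a:
            if x in rest:
                rest.remove(x)
                shared += 1
        mism += 2 - shared
    if compared == 0:
        raise ValueError("incomparable: zero co-typed loci")
    return compared, mism


@dataclass
class MatchReport:
    pairs: list[tuple[str, str, int, int]]  # (id_a, id_b, loci_compared, mismatches)
    groups: list[list[str]]
    representative: dict[str, str]  # group member -> representative id
    low_overlap_pairs: list[tuple[str, str, int, int]] = field(default_factory=list)
    non_clique_groups: list[list[str]] = field(default_factory=list)

    def multi_member_groups(self) -> list[list[str]]:
        return [g for g in self.groups if len(g) > 1]


def find_duplicates(table: GenotypeTable, loci: Optional[Sequence[str]] = None,
                    max_mismatch: int = 2, min_overlap: int = 6,
                    metadata: Optional[dict[str, AccessionMeta]] = None) -> MatchReport:
    """Partition accessions into identity groups.

    Pairs within ``max_mismatch`` alleles are linked; groups are the
    transitive closure of the links. Pairs with fewer than ``min_overlap``
    co-typed loci are reported but never merged. The representative of a
    group is its true-to-type member when metadata says so, else the
    lexicographically first ID.
    """
    loci = list(loci) if loci is not None else table.loci.names
    ids = table.individuals
    rows = {i: table.genotype_row(i) for i in ids}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    matched, low_overlap = [], []
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            try:
                compared, mism = pairwise_mismatch(rows[a], rows[b], loci)
            except ValueError:
                continue
            if mism <= max_mismatch:
                if compared < min_overlap:
                    low_overlap.append((a, b, compared, mism))
                    continue
                matched.append((a, b, compared, mism))
                adj[a].add(b)
                adj[b].add(a)
                parent[find(a)] = find(b)

    groups_map: dict[str, list[str]] = {}
    for i in ids:
        groups_map.setdefault(find(i), []).append(i)
    groups = [sorted(g) for g in groups_map.values()]
    groups.sort(key=lambda g: g[0])

    non_clique = [g for g in groups if len(g) > 2 and any(
        b not in adj[a] for ai, a in enumerate(g) for b in g[ai + 1:])]

    rep: dict[str, str] = {}
    for g in groups:
        ttt = [x for x in g if metadata and x in metadata and metadata[x].true_to_type]
        chosen = sorted(ttt)[0] if ttt else g[0]
        for x in g:
            rep[x] = chosen
    return MatchReport(matched, groups, rep, low_overlap, non_clique)


def non_redundant_set(report: MatchReport) -> list[str]:
    """One representative per identity group, in group order."""
    return [report.representative[g[0]] for g in report.groups]


def classify_status(report: MatchReport, metadata: dict[str, AccessionMeta],
                    external_matches: Optional[dict[str, list[tuple[str, str]]]] = None,
                    ) -> dict[str, AccessionStatus]:
    """Assign each accession one of the nine curation status classes.

    Deterministic cascade, most specific first: sampling errors and
    mislabelings flagged in metadata (IX, VIII), intruders (VI), members of
    an internal identity group other than its representative (II), external
    synonym in a neighboring (III) or distant (IV) country, documented
    foreign origin (V), then unique profiles split by record completeness
    into I (full ampelographic record) and VII (questionable). Accessions
    with conflicting flags come back as "unresolved".
    """
    external_matches = external_matches or {}
    out: dict[str, AccessionStatus] = {}
    for acc_id in report.representative:
        meta = metadata.get(acc_id, AccessionMeta(id=acc_id))
        flags = getattr(meta, "flags", None) or set()
        conflicting = {"intruder", "mislabeled", "sampling_error"} & flags
        if len(conflicting) > 1:
            out[acc_id] = AccessionStatus.UNRESOLVED
            continue
        if "sampling_error" in flags:
            out[acc_id] = AccessionStatus.SAMPLING_ERROR
            continue
        if "mislabeled" in flags:
            out[acc_id] = AccessionStatus.MISLABELED
            continue
        if "intruder" in flags:
            out[acc_id] = AccessionStatus.INTRUDER
            continue
        if report.representative[acc_id] != acc_id:
            out[acc_id] = AccessionStatus.SYNONYM_INTERNAL
            continue
        ext = external_matches.get(acc_id, [])
        if ext:
            countries = {c for _, c in ext}
            if countries & NEIGHBOR_COUNTRIES:
                out[acc_id] = AccessionStatus.SYNONYM_NEIGHBOR
            else:
                out[acc_id] = AccessionStatus.SYNONYM_DISTANT
            continue
        if meta.region is not None and meta.region.value == "foreign":
            out[acc_id] = AccessionStatus.KNOWN_FOREIGN
            continue
        has_record = bool(meta.declared_name) and bool(meta.collection)
        out[acc_id] = AccessionStatus.UNIQUE if has_record else AccessionStatus.QUESTIONABLE
    return out
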