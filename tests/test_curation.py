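import pytest

from grapegen import (AccessionMeta, classify_status, find_duplicates,
                      non_redundant_set, pairwise_mismatch)
from grapegen.genotypes import AccessionStatus, Region
from conftest import make_table


def test_pairwise_mismatch_counts_alleles():
    g1 = {"L0": (100, 102), "L1": (104, 104), "L2": None}
    g2 = {"L0": (100, 104), "L1": (104, 104), "L2": (100, 100)}
    compared, mism = pairwise_mismatch(g1, g2, ["L0", "L1", "L2"])
    assert (compared, mism) == (2, 1)  # L2 not co-typed; L0 shares one allele


def test_pairwise_mismatch_incomparable():
    with pytest.raises(ValueError, match="incomparable"):
        pairwise_mismatch({"L0": None}, {"L0": (1, 2)}, ["L0"])


def _trio_table():
    # A == B exactly; C differs from both by 3 alleles
    return make_table([
        [(100, 102), (104, 106), (108, 108)],
        [(100, 102), (104, 106), (108, 108)],
        [(100, 100), (104, 104), (110, 110)],
    ], ids=["A", "B", "C"])


def test_find_duplicates_groups_and_representative():
    t = _trio_table()
    rep = find_duplicates(t, max_mismatch=2, min_overlap=2)
    groups = rep.multi_member_groups()
    assert groups == [["A", "B"]]
    assert set(non_redundant_set(rep)) == {"A", "C"}


def test_duplicate_tolerance_allows_somatic_variants():
    t = make_table([
        [(100, 102), (104, 106)],
        [(100, 104), (104, 106)],  # one allele shifted
    ], ids=["A", "A_clone"])
    rep = find_duplicates(t, max_mismatch=2, min_overlap=2)
    assert rep.multi_member_groups() == [["A", "A_clone"]]
    rep0 = find_duplicates(t, max_mismatch=0, min_overlap=2)
    assert rep0.multi_member_groups() == []


def test_low_overlap_pairs_not_merged():
    t = make_table([
        [(100, 102), None, None],
        [(100, 102), None, None],
    ], ids=["A", "B"])
    rep = find_duplicates(t, max_mismatch=2, min_overlap=2)
    assert rep.multi_member_groups() == []
    assert rep.low_overlap_pairs


def test_transitive_closure_merges_chains():
    # A~B and B~C within tolerance, A~C outside: still one group (flagged)
    t = make_table([
        [(100, 100), (104, 104), (108, 108)],
        [(100, 102), (104, 104), (108, 108)],
        [(100, 102), (104, 106), (108, 108)],
    ], ids=["A", "B", "C"])
    rep = find_duplicates(t, max_mismatch=1, min_overlap=2)
    assert rep.multi_member_groups() == [["A", "B", "C"]]
    assert rep.non_clique_groups


def test_classify_status_cascade():
    t = _trio_table()
    rep = find_duplicates(t, max_mismatch=2, min_overlap=2)
    meta = {
        "A": AccessionMeta(id="A", declared_name="plavac",
                           collection="coll1", region=Region.DALMATIA),
        "B": AccessionMeta(id="B", declared_name="plavac mali",
                           collection="coll1", region=Region.DALMATIA),
        "C": AccessionMeta(id="C"),
    }
    out = classify_status(rep, meta)
    assert out["A"] == AccessionStatus.UNIQUE
    assert out["B"] == AccessionStatus.SYNONYM_INTERNAL
    assert out["C"] == AccessionStatus.QUESTIONABLE


def test_classify_status_flags_and_external():
    t = _trio_table()
    rep = find_duplicates(t, max_mismatch=2, min_overlap=2)
    meta = {
        "A": AccessionMeta(id="A", declared_name="x", collection="c",
                           flags={"sampling_error"}),
        "C": AccessionMeta(id="C", declared_name="y", collection="c"),
    }
    out = classify_status(rep, meta,
                          external_matches={"C": [("Refosco", "Italy")]})
    assert out["A"] == AccessionStatus.SAMPLING_ERROR
    assert out["C"] == AccessionStatus.SYNONYM_NEIGHBOR
    out2 = classify_status(rep, meta,
                           external_matches={"C": [("Listan", "Spain")]})
    assert out2["C"] == AccessionStatus.SYNONYM_DISTANT


def test_conflicting_flags_unresolved():
    t = _trio_table()
    rep = find_duplicates(t, max_mismatch=2, min_overlap=2)
    meta = {"A": AccessionMeta(id="A", flags={"intruder", "mislabeled"})}
    out = classify_status(rep, meta)
    assert out["A"] == AccessionStatus.UNRESOLVED
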