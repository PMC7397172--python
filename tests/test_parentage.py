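import math

import numpy as np
import pandas as pd
import pytest

from grapegen import (ParentageEngine, SimulationConfig, allele_frequencies,
                      assign_parentage, flag_null_loci, gen_pedigree,
                      halfkin_screen, simulate_critical_lod,
                      transition_probability)
from grapegen.diversity import AlleleFrequencyTable
from grapegen.parentage import _precision_threshold
from conftest import make_table


def _freqs(p_by_locus: dict, n: int = 100) -> AlleleFrequencyTable:
    return AlleleFrequencyTable(
        freqs=p_by_locus,
        n_typed={l: n for l in p_by_locus},
        counts={l: {a: round(2 * n * f) for a, f in fmap.items()}
                for l, fmap in p_by_locus.items()},
    )


def test_duo_homozygous_parent_lod_is_inverse_frequency():
    """Parent (A,A), offspring (A,B), no error: LOD = ln(1 / (2 p_A))."""
    pA, pB = 0.3, 0.2
    freqs = _freqs({"L0": {100: pA, 102: pB, 104: 0.5}})
    eng = ParentageEngine(freqs, ["L0"], eps=0.0)
    lod, mism, comp = transition_probability(
        eng, {"L0": (100, 102)}, {"L0": (100, 100)})
    assert comp == 1 and mism == 0
    assert lod == pytest.approx(math.log(1.0 / (2 * pA)))


def test_trio_homozygous_parents_lod():
    """Parents (A,A) x (B,B), offspring (A,B): LOD = ln(1/(2 pA pB))."""
    pA, pB = 0.3, 0.2
    freqs = _freqs({"L0": {100: pA, 102: pB, 104: 0.5}})
    eng = ParentageEngine(freqs, ["L0"], eps=0.0)
    lod, mism, comp = transition_probability(
        eng, {"L0": (100, 102)}, {"L0": (100, 100)}, {"L0": (102, 102)})
    assert lod == pytest.approx(math.log(1.0 / (2 * pA * pB)))
    assert mism == 0


def test_exclusion_without_error_gives_minus_infinity():
    freqs = _freqs({"L0": {100: 0.4, 102: 0.4, 104: 0.2}})
    eng = ParentageEngine(freqs, ["L0"], eps=0.0)
    lod, mism, comp = transition_probability(
        eng, {"L0": (100, 102)}, {"L0": (104, 104)})
    assert lod == -math.inf and mism == 1


def test_error_model_smooths_exclusion():
    """With eps > 0 an excluding locus contributes a finite penalty."""
    freqs = _freqs({"L0": {100: 0.4, 102: 0.4, 104: 0.2}})
    eng = ParentageEngine(freqs, ["L0"], eps=0.01)
    lod, mism, comp = transition_probability(
        eng, {"L0": (100, 102)}, {"L0": (104, 104)})
    # L1 = (1 - q^2) * HW, so LOD = ln(1 - q^2)
    assert lod == pytest.approx(math.log(1.0 - 0.99 ** 2))
    assert mism == 1


def test_duo_likelihood_coefficients_sum_to_one():
    # mixture weights of the error model must be a probability partition
    for eps in (0.0, 0.01, 0.1):
        q = 1 - eps
        assert q * q + (1 - q * q) == pytest.approx(1.0)
        assert q ** 3 + 2 * q * q * eps + (q * eps ** 2 + eps) == pytest.approx(1.0)


def test_lod_increases_with_rarer_shared_allele():
    freqs = _freqs({"L0": {100: 0.05, 102: 0.45, 104: 0.5},
                    "L1": {100: 0.40, 102: 0.10, 104: 0.5}})
    eng = ParentageEngine(freqs, ["L0"], eps=0.0)
    rare, _, _ = transition_probability(
        eng, {"L0": (100, 102)}, {"L0": (100, 100)})
    eng2 = ParentageEngine(freqs, ["L1"], eps=0.0)
    common, _, _ = transition_probability(
        eng2, {"L1": (100, 102)}, {"L1": (100, 100)})
    assert rare > common


def test_missing_loci_are_skipped_not_penalized():
    freqs = _freqs({"L0": {100: 0.5, 102: 0.5}, "L1": {100: 0.5, 102: 0.5}})
    eng = ParentageEngine(freqs, ["L0", "L1"], eps=0.0)
    lod, mism, comp = transition_probability(
        eng, {"L0": (100, 102), "L1": None}, {"L0": (100, 100), "L1": (102, 102)})
    assert comp == 1 and mism == 0


def test_precision_threshold_definition():
    lods = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
    correct = np.array([1, 1, 1, 0, 1])
    # prefixes: precision 1, 1, 1, 0.75, 0.8 -> at level 0.8 keep all 5
    assert _precision_threshold(lods, correct, 0.80) == 2.0
    # at level 0.95 only the first three qualify
    assert _precision_threshold(lods, correct, 0.95) == 6.0
    assert _precision_threshold(lods, np.zeros(5), 0.5) == math.inf


def test_flag_null_loci_threshold():
    df = pd.DataFrame({"locus": ["a", "b", "c"],
                       "fnull": [0.05, 0.11, None]})
    assert flag_null_loci(df, 0.1) == ["b"]


def test_planted_trios_recovered(clean_pop):
    table, truth = clean_pop
    off, ped = gen_pedigree(table, 25, seed=501)
    freqs = allele_frequencies(table)
    sim = SimulationConfig(n_offspring=800, prop_sampled=1.0, error_rate=0.01)
    crit = simulate_critical_lod(freqs, table, sim, seed=502)
    assert math.isfinite(crit["strict95"])
    res = assign_parentage(off, table, freqs, crit, eps=0.01)
    trios = [r for r in res if len(r.parents) == 2]
    right = sum(set(r.parents) == set(ped.pedigree[r.offspring]) for r in trios)
    assert right == len(trios)          # nothing wrongly assigned
    assert right >= 20                   # most planted trios recovered


def test_offspring_never_assigned_to_itself(clean_pop):
    table, _ = clean_pop
    freqs = allele_frequencies(table)
    res = assign_parentage(table, table, freqs, critical=0.0, eps=0.01)
    for r in res:
        assert r.offspring not in r.parents


def test_halfkin_screen_covers_parent_offspring(clean_pop):
    from grapegen import concat_tables
    table, _ = clean_pop
    off, ped = gen_pedigree(table, 10, seed=503)
    freqs = allele_frequencies(table)
    both = concat_tables(table, off)
    pairs = halfkin_screen(both, freqs)
    found = {frozenset((k.id_a, k.id_b)) for k in pairs}
    for child, parents in ped.pedigree.items():
        for p in parents:
            assert frozenset((child, p)) in found
    # sorted by descending LOD
    lods = [k.lod for k in pairs]
    assert lods == sorted(lods, reverse=True)


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(prop_sampled=1.5)
    with pytest.raises(ValueError):
        ParentageEngine(_freqs({"L0": {1: 1.0}}), ["L0"], eps=0.7)
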