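"""Shared fixtures and small genotype-table builders."""

from __future__ import annotations

import numpy as np
import pytest

from grapegen import (Category, GenotypeTable, MarkerDef, MarkerPanel,
                      MarkerSystem, SimPopConfig, gen_population)


def ssr_panel(n: int, prefix: str = "L", motif: int = 2,
              category: Category = Category.CAT1) -> MarkerPanel:
    return MarkerPanel([MarkerDef(f"{prefix}{j}", MarkerSystem.SSR,
                                  motif_length=motif, category=category)
                        for j in range(n)])


def make_table(calls: list[list], ids=None, panel: MarkerPanel = None,
               ploidy: int = 2) -> GenotypeTable:
    """Build a table from nested call lists (tuples or None)."""
    n = len(calls)
    l = len(calls[0])
    ids = ids or [f"I{i}" for i in range(n)]
    panel = panel or ssr_panel(l)
    return GenotypeTable(ids, panel, calls, ploidy)


def random_table(rng: np.random.Generator, n: int, n_loci: int,
                 n_alleles: int = 5, missing: float = 0.0) -> GenotypeTable:
    """Random diploid table over integer alleles 100, 102, ... ."""
    alleles = [100 + 2 * a for a in range(n_alleles)]
    calls = []
    for _ in range(n):
        row = []
        for _ in range(n_loci):
            if missing and rng.random() < missing:
                row.append(None)
            else:
                row.append(tuple(sorted(rng.choice(alleles, 2))))
        calls.append(row)
    return make_table(calls)


@pytest.fixture(scope="session")
def two_pool():
    """2-pool synthetic population used across structure/AMOVA tests."""
    cfg = SimPopConfig(seed=4201, n_pools=2, n_per_pool=25, n_loci=12,
                       n_snp=0, missing_rate=0.0, error_rate=0.0)
    return gen_population(cfg)


@pytest.fixture(scope="session")
def clean_pop():
    """Single-pool, error- and gap-free population for parentage tests."""
    cfg = SimPopConfig(seed=4202, n_pools=1, n_per_pool=40, n_loci=14,
                       n_snp=0, missing_rate=0.0, error_rate=0.0)
    return gen_population(cfg)
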