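"""Config-driven end-to-end run: fingerprint, dedupe, diversity statistics,
distance/tree, structure/AMOVA, parentage and chlorotype reports.

One declarative config drives all stages; every stochastic stage carries an
explicit seed so a rerun with the same config reproduces every numeric
output exactly. Artifacts are CSV/TSV/Newick with a provenance comment
header (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .admixture import align_replicates, assign_membership, evanno, run_admixture
from .amova import amova
from .chlorotype import ChlorotypeMap, assign_chlorotype, chlorotype_frequencies, designate_mother
from .curation import find_duplicates, non_redundant_set
from .distance import psa_distance, to_newick, upgma, write_distance_csv
from .diversity import allele_frequencies, panel_summary, stats_table
from .genotypes import GenotypeTable
from .io import read_genotype_csv
from .markers import Category, MarkerPanel, MarkerSystem, read_panel_csv
from .parentage import SimulationConfig, assign_parentage, flag_null_loci, simulate_critical_lod

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str = ""
    panel: str = ""
    cp_genotypes: Optional[str] = None
    chlorotype_map: Optional[str] = None
    out_dir: str = "grapegen_out"
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "dedupe", "stats", "tree", "structure", "amova", "parentage", "chlorotype"])
    # thresholds
    duplicate_tolerance: int = 2
    q_threshold: float = 0.75
    mismatch_fraction: float = 0.05
    error_rate: float = 0.01
    fnull_exclude: float = 0.1
    # structure settings
    k_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    structure_reps: int = 3
    structure_iters: int = 2000
    structure_burnin: int = 2000
    freq_model: str = "correlated"
    # parentage simulation
    n_sim_offspring: int = 10_000
    prop_sampled: float = 0.01
    # seeds
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        # hash only what affects results, not where they are written
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha1(json.dumps(d, sort_keys=True)
                            .encode()).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path: Path, cfg: RunConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grapegen {__version__} seed={cfg.seed} config={cfg.digest()}\n")
        df.to_csv(fh, index=kw.pop("index", False), **kw)


def run_pipeline(cfg: RunConfig,
                 table: Optional[GenotypeTable] = None,
                 cp_table: Optional[GenotypeTable] = None) -> dict[str, Path]:
    """Execute the configured stages in order; returns artifact paths.

    ``table``/``cp_table`` may be passed directly (e.g. from the synthetic
    generator) instead of reading the configured CSV paths. A stage failure
    aborts with the stage named; artifacts written so far are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if table is None:
        panel = read_panel_csv(cfg.panel)
        nuclear_panel = MarkerPanel([m for m in panel
                                     if m.category != Category.CAT4])
        table = read_genotype_csv(cfg.genotypes, nuclear_panel)
    panel = table.loci
    stage = "load"
    log.info("loaded %d accessions x %d loci", table.n_individuals, table.n_loci)

    try:
        # ---------------- dedupe ----------------
        nr_table = table
        if "dedupe" in cfg.stages:
            stage = "dedupe"
            cat1 = panel.by_category(Category.CAT1)
            loci = cat1.names if len(cat1) else panel.names
            report = find_duplicates(table, loci, max_mismatch=cfg.duplicate_tolerance)
            rows = pd.DataFrame(report.pairs,
                                columns=["id_a", "id_b", "loci_compared", "mismatches"])
            p = out / "duplicates.csv"
            _write_with_header(rows, p, cfg)
            artifacts["duplicates"] = p
            keep = non_redundant_set(report)
            nr_table = table.subset(individuals=keep)
            log.info("dedupe: %d accessions in, %d duplicates removed, %d unique out",
                     table.n_individuals, table.n_individuals - len(keep), len(keep))

        # ---------------- stats ----------------
        stats = None
        if "stats" in cfg.stages:
            stage = "stats"
            nuclear = [m.name for m in panel
                       if m.system in (MarkerSystem.SSR, MarkerSystem.SNP)]
            stats = stats_table(nr_table.subset(loci=nuclear), hw_seed=cfg.seed)
            p = out / "locus_stats.csv"
            _write_with_header(stats, p, cfg)
            artifacts["locus_stats"] = p
            summary = panel_summary(stats)
            (out / "panel_summary.json").write_text(json.dumps(summary, indent=2))
            artifacts["panel_summary"] = out / "panel_summary.json"

        # ---------------- distance / tree ----------------
        dm = None
        if "tree" in cfg.stages:
            stage = "tree"
            ssr = [m.name for m in panel if m.system == MarkerSystem.SSR]
            dm = psa_distance(nr_table, ssr or None)
            p = out / "distance.csv"
            write_distance_csv(dm, p)
            artifacts["distance"] = p
            if dm.complete:
                tree = upgma(dm)
                p = out / "upgma.nwk"
                p.write_text(to_newick(tree) + "\n")
                artifacts["tree"] = p
            else:
                log.warning("distance matrix incomplete; tree stage skipped")

        # ---------------- structure ----------------
        groups = None
        if "structure" in cfg.stages:
            stage = "structure"
            nuclear = [m.name for m in panel
                       if m.system in (MarkerSystem.SSR, MarkerSystem.SNP)]
            sub = nr_table.subset(loci=nuclear)
            results = []
            for k in cfg.k_range:
                for rep in range(cfg.structure_reps):
                    results.append(run_admixture(
                        sub, k, iters=cfg.structure_iters,
                        burnin=cfg.structure_burnin,
                        seed=cfg.seed * 10_000 + k * 100 + rep,
                        freq_model=cfg.freq_model))
            if len(cfg.k_range) >= 3 and cfg.structure_reps >= 2:
                ev = evanno(results)
                p = out / "evanno.csv"
                _write_with_header(ev.reset_index(), p, cfg)
                artifacts["evanno"] = p
                best_k = ev.attrs.get("suggested_K") or int(
                    ev["mean_lnPXK"].idxmax())
            else:
                best_k = max(cfg.k_range)
            qs = [r.Q for r in results if r.K == best_k]
            _, mean_q, _ = align_replicates(qs, reps=50, seed=cfg.seed)
            qdf = pd.DataFrame(mean_q, index=sub.individuals,
                               columns=[f"Q{k + 1}" for k in range(best_k)])
            p = out / "q_matrix.tsv"
            qdf.to_csv(p, sep="\t")
            artifacts["q_matrix"] = p
            labels = assign_membership(mean_q, cfg.q_threshold)
            groups = {}
            for ind, lab in zip(sub.individuals, labels):
                if lab != "admixed":
                    groups.setdefault(lab, []).append(ind)

        # ---------------- AMOVA ----------------
        if "amova" in cfg.stages and groups and len(groups) >= 2 and dm is not None:
            stage = "amova"
            try:
                res = amova(dm, groups, n_perm=999, seed=cfg.seed)
                txt = [f"Phi_PT = {res.phi_pt:.4f}  p = {res.p_value:.4g} "
                       f"({res.n_permutations} permutations)"]
                if res.pairwise_phi:
                    for (a, b), v in res.pairwise_phi.items():
                        txt.append(f"  {a} vs {b}: Phi = {v:.4f} "
                                   f"p = {res.pairwise_p[(a, b)]:.4g}")
                p = out / "amova.txt"
                p.write_text("\n".join(txt) + "\n")
                artifacts["amova"] = p
            except ValueError as e:
                log.warning("amova skipped: %s", e)

        # ---------------- parentage ----------------
        trios = []
        if "parentage" in cfg.stages:
            stage = "parentage"
            ssr = [m.name for m in panel if m.system == MarkerSystem.SSR
                   and m.category in (Category.CAT1, Category.CAT2)]
            if stats is not None:
                bad = set(flag_null_loci(stats, cfg.fnull_exclude))
                ssr = [l for l in ssr if l not in bad]
            sub = nr_table.subset(loci=ssr)
            freqs = allele_frequencies(sub)
            sim = SimulationConfig(n_offspring=cfg.n_sim_offspring,
                                   prop_sampled=cfg.prop_sampled,
                                   error_rate=cfg.error_rate)
            critical = simulate_critical_lod(freqs, sub, sim, seed=cfg.seed)
            results = assign_parentage(sub, sub, freqs, critical,
                                       eps=cfg.error_rate,
                                       max_mismatch_frac=cfg.mismatch_fraction)
            rows = pd.DataFrame([{
                "offspring": r.offspring,
                "parent1": r.parents[0],
                "parent2": r.parents[1] if len(r.parents) > 1 else "",
                "loci": r.loci_compared, "mismatches": r.mismatches,
                "lod": round(r.lod, 2), "confidence": r.confidence,
                "maternal": r.maternal} for r in results])
            p = out / "parentage.csv"
            _write_with_header(rows, p, cfg)
            artifacts["parentage"] = p
            trios = [r for r in results if len(r.parents) == 2]

        # ---------------- chlorotype ----------------
        if "chlorotype" in cfg.stages:
            stage = "chlorotype"
            if cp_table is None and cfg.cp_genotypes:
                cmap = (ChlorotypeMap.from_csv(cfg.chlorotype_map)
                        if cfg.chlorotype_map else ChlorotypeMap.default())
                cp_panel = MarkerPanel([m for m in read_panel_csv(cfg.panel)
                                        if m.category == Category.CAT4])
                cp_table = read_genotype_csv(cfg.cp_genotypes, cp_panel)
            if cp_table is None:
                log.info("no chlorotype data configured; stage skipped")
            else:
                cmap = (ChlorotypeMap.from_csv(cfg.chlorotype_map)
                        if cfg.chlorotype_map else ChlorotypeMap.default())
                assigns = assign_chlorotype(cp_table, cmap)
                rows = pd.DataFrame(sorted(assigns.items()),
                                    columns=["id", "chlorotype"])
                p = out / "chlorotypes.csv"
                _write_with_header(rows, p, cfg)
                artifacts["chlorotypes"] = p
                freq = chlorotype_frequencies(assigns)
                p = out / "chlorotype_frequencies.csv"
                _write_with_header(freq, p, cfg)
                artifacts["chlorotype_frequencies"] = p
                for r in trios:
                    r.maternal = designate_mother(
                        (r.offspring, r.parents[0], r.parents[1]), assigns)
                if trios and "parentage" in artifacts:
                    rows = pd.DataFrame([{
                        "offspring": r.offspring, "parent1": r.parents[0],
                        "parent2": r.parents[1], "loci": r.loci_compared,
                        "mismatches": r.mismatches, "lod": round(r.lod, 2),
                        "confidence": r.confidence, "maternal": r.maternal}
                        for r in trios])
                    _write_with_header(rows, artifacts["parentage"], cfg)
    except Exception:
        log.error("pipeline aborted in stage %r; partial outputs kept in %s",
                  stage, out)
        raise
    return artifacts
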