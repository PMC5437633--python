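"""End-to-end orchestration of the synthetic microsatellite-evolution run.

``run_pipeline`` executes the stages in dependency order —

    simulate -> scan -> imperfection analyses -> TE proximity
             -> conservation mapping -> decay / relative abundance

— writing every stage's outputs under the manifest's output directory and a
machine-readable ``summary.json`` at the end.  A single global seed is
fanned out to per-stage seeds through ``numpy.random.SeedSequence`` so
stages stay reproducible without coupling.  Completed stages are detected
by their output files and skipped on rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .align import AlignmentParams
from .conserve import (build_library, conservation_proportions,
                       map_conservation, self_uniqueness_filter)
from .decay import estimate_decay, relative_abundance
from .detect import DetectionConfig, exclude_compounds, scan_genome, \
    summarize_density
from .imperfection import (build_datasets, canonical_ordination,
                           pairwise_length_correlations, permanova,
                           regress_mismatch_on_length)
from .io import (write_circos_links, write_conservation_tsv, write_fasta,
                 write_gff3, write_json, write_loci_tsv, write_truth_tsv,
                 read_fasta, read_loci_tsv)
from .simulate import (EvolutionScenario, SimulationConfig, evolve_tetraploid,
                       generate_genome)
from .te import correlate_te_repeats, count_tes_near_loci

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("ssrevol")


@dataclass
class RunManifest:
    """Declarative description of one synthetic end-to-end run."""

    seed: int = 0
    output_dir: str = "ssrevol_run"
    simulation_a: dict = field(default_factory=dict)
    simulation_d: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    n_permutations: int = 999
    comparisons: list = field(default_factory=lambda: [
        {"query": "A2", "subgenome": "A_T"},
        {"query": "D5", "subgenome": "D_T"},
    ])

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown manifest keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        declared = {"A2", "D5"}
        subgenomes = {"A_T", "D_T"}
        for comp in self.comparisons:
            if comp.get("query") not in declared:
                raise ValueError(
                    f"comparison references undeclared genome "
                    f"{comp.get('query')!r}")
            if comp.get("subgenome") not in subgenomes:
                raise ValueError(
                    f"comparison references unknown subgenome "
                    f"{comp.get('subgenome')!r}")


def _stage_seed(seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(seed)
    return int(ss.generate_state(stage + 1)[stage] % (2 ** 31))


def run_pipeline(manifest: RunManifest) -> dict:
    """Run all stages; returns the summary dict (also written as JSON)."""
    manifest.validate()
    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(manifest, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(manifest: RunManifest, out: Path) -> dict:
    det_cfg = DetectionConfig(**manifest.detection)
    log.info("ssrevol %s seed=%d detection=%s", __version__, manifest.seed,
             det_cfg)
    sim_seed_a = _stage_seed(manifest.seed, 0)
    sim_seed_d = _stage_seed(manifest.seed, 1)
    evo_seed = _stage_seed(manifest.seed, 2)
    stat_seed = _stage_seed(manifest.seed, 3)

    # --- stage: simulate -------------------------------------------------
    genomes: dict[str, dict[str, str]] = {}
    fasta_done = all((out / f"{g}.fasta").exists()
                     for g in ("A2", "D5", "A_T", "D_T"))
    cfg_a = SimulationConfig(**{"seed": sim_seed_a, **manifest.simulation_a,
                                "detection": det_cfg})
    cfg_d = SimulationConfig(**{"seed": sim_seed_d, **manifest.simulation_d,
                                "detection": det_cfg})
    if fasta_done:
        log.info("simulate: outputs present, skipping")
        for g in ("A2", "D5", "A_T", "D_T"):
            genomes[g] = read_fasta(out / f"{g}.fasta")
        tes = {"A2": [], "D5": []}
        sims = None
    else:
        log.info("simulate: generating progenitors and tetraploid")
        sim_a = generate_genome(cfg_a)
        sim_d = generate_genome(cfg_d)
        scenario = EvolutionScenario(**manifest.scenario)
        tet = evolve_tetraploid(sim_a, sim_d, scenario, seed=evo_seed)
        genomes["A2"] = sim_a.sequences
        genomes["D5"] = sim_d.sequences
        genomes["A_T"] = {c: s for c, s in tet.sequences.items()
                          if c.startswith("A_T")}
        genomes["D_T"] = {c: s for c, s in tet.sequences.items()
                          if c.startswith("D_T")}
        for g in genomes:
            write_fasta(genomes[g], out / f"{g}.fasta")
        write_truth_tsv(sim_a.truth, out / "A2.truth.tsv")
        write_truth_tsv(sim_d.truth, out / "D5.truth.tsv")
        write_gff3(sim_a.tes, out / "A2.te.gff3")
        write_gff3(sim_d.tes, out / "D5.te.gff3")
        tes = {"A2": sim_a.tes, "D5": sim_d.tes}
        sims = {"A2": sim_a, "D5": sim_d}

    # --- stage: scan ------------------------------------------------------
    loci = {}
    removed = {}
    for g, seqs in genomes.items():
        loci_path = out / f"{g}.loci.tsv"
        if loci_path.exists():
            loci[g] = read_loci_tsv(loci_path)
            removed[g] = []
            log.info("scan %s: output present, skipping", g)
            continue
        raw = scan_genome(seqs, det_cfg)
        loci[g], removed[g] = exclude_compounds(raw, det_cfg)
        write_loci_tsv(loci[g], loci_path)
        log.info("scan %s: %d loci (%d compound-excluded)", g, len(loci[g]),
                 len(removed[g]))
    densities = {}
    for g, seqs in genomes.items():
        lengths = {c: len(s) for c, s in seqs.items()}
        genome_df, chrom_df = summarize_density(loci[g], lengths)
        genome_df.to_csv(out / f"{g}.density.tsv", sep="\t", index=False)
        chrom_df.to_csv(out / f"{g}.density.per_chrom.tsv", sep="\t",
                        index=False)
        densities[g] = genome_df

    # --- stage: imperfection ---------------------------------------------
    ds1, ds2 = build_datasets(loci)
    ds1.to_csv(out / "dataset_I.tsv", sep="\t")
    ds2.to_csv(out / "dataset_II.tsv", sep="\t")
    stats_summary: dict = {}
    try:
        blockA = ds1.xs(0, axis=1, level="mismatch_count").to_numpy()
        blockB = ds1.xs(1, axis=1, level="mismatch_count").to_numpy()
        res, _, _ = canonical_ordination(
            blockA, blockB, n_permutations=manifest.n_permutations,
            seed=stat_seed)
        stats_summary["canonical_ordination_dataset_I"] = {
            "statistic": res.statistic, "p_value": res.p_value}
    except ValueError as exc:
        stats_summary["canonical_ordination_dataset_I"] = {"error": str(exc)}
    # PERMANOVA on long-repeat frequencies: rows = (length, mismatch) cells
    lengths = list(range(30, 85, 5))
    rows, lab_len, lab_mm = [], [], []
    for L in lengths:
        for m in (1, 2, 3, 4):
            rows.append([sum(1 for l in loci[g]
                             if l.mismatch_count == m
                             and L <= l.repeat_length < L + 5)
                         for g in loci])
            lab_len.append(L)
            lab_mm.append(m)
    perm = permanova(np.array(rows, dtype=float),
                     {"repeat_length": lab_len, "mismatch": lab_mm},
                     n_permutations=manifest.n_permutations, seed=stat_seed)
    stats_summary["permanova"] = {
        f: {"pseudo_F": r.statistic, "p_value": r.p_value,
            "degenerate": r.degenerate}
        for f, r in perm.items()}
    corr = pairwise_length_correlations(loci)
    corr.to_csv(out / "pairwise_correlations.tsv", sep="\t", index=False)
    regression = {}
    for g in loci:
        try:
            fit = regress_mismatch_on_length(loci[g])
            regression[g] = {"slope": fit.slope, "intercept": fit.intercept,
                             "r_squared": fit.r_squared,
                             "p_value": fit.p_value, "n": fit.n}
        except ValueError as exc:
            regression[g] = {"error": str(exc)}
    stats_summary["mismatch_length_regression"] = regression

    # --- stage: TE proximity ---------------------------------------------
    te_summary = {}
    for g, te_list in tes.items():
        if not te_list:
            continue
        rec = count_tes_near_loci(loci[g], te_list)
        rec.to_csv(out / f"{g}.te_proximity.tsv", sep="\t", index=False)
        if len(rec) >= 3:
            te_summary[g] = correlate_te_repeats(rec)
    stats_summary["te_proximity"] = te_summary

    # --- stage: conservation + decay -------------------------------------
    aln = AlignmentParams()
    conservation = {}
    decay = {}
    for comp in manifest.comparisons:
        q, sub = comp["query"], comp["subgenome"]
        tag = f"{q}_vs_{sub}"
        lib_q = build_library(loci[q], genomes[q], source_genome=q)
        lib_q, _ = self_uniqueness_filter(lib_q, aln)
        lib_s = build_library(loci[sub], genomes[sub], source_genome=sub)
        lib_s, _ = self_uniqueness_filter(lib_s, aln)
        records = map_conservation(lib_q, lib_s, aln)
        write_conservation_tsv(records, out / f"{tag}.conservation.tsv")
        write_circos_links(records, out / f"{tag}.links.tsv")
        props = conservation_proportions(records)
        props.to_csv(out / f"{tag}.proportions.tsv", sep="\t", index=False)
        conservation[tag] = {
            r["motif_length"]: r["proportion"]
            for r in props.to_dict("records")}
        by_class = {r["motif_length"]: r["proportion"]
                    for r in props.to_dict("records")
                    if r["defined"] and r["motif_length"] != "all"}
        overall = conservation[tag].get("all")
        if overall and overall > 0:
            t = manifest.scenario.get("divergence_time", 6.0)
            ests = estimate_decay(by_class, overall, t)
            decay[tag] = {e.label: {
                "conserved_fraction": e.conserved_fraction,
                "decay_rate": e.decay_rate,
                "relative_decay": e.relative_decay,
                "relative_loss": e.relative_loss} for e in ests}
        log.info("conserve %s: %s", tag, conservation[tag])
    stats_summary["conservation"] = conservation
    stats_summary["decay"] = decay

    # --- stage: relative abundance (subgenome vs progenitor) -------------
    rel = {}
    for comp in manifest.comparisons:
        q, sub = comp["query"], comp["subgenome"]
        focal = {str(r.motif_length): r.density_per_mb
                 for r in densities[sub].itertuples()}
        ref = {str(r.motif_length): r.density_per_mb
               for r in densities[q].itertuples()}
        tab = relative_abundance(focal, ref)
        tab.to_csv(out / f"{sub}_over_{q}.relative_abundance.tsv", sep="\t",
                   index=False)
        rel[f"{sub}_over_{q}"] = {
            r["label"]: r["relative_abundance"]
            for r in tab.to_dict("records") if r["defined"]}
    stats_summary["relative_abundance"] = rel

    summary = {
        "version": __version__,
        "seed": manifest.seed,
        "n_loci": {g: len(v) for g, v in loci.items()},
        "results": stats_summary,
    }
    write_json(summary, out / "summary.json")
    log.info("pipeline complete")
    return summary
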