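"""End-to-end orchestration: simulate -> call -> stats -> select -> analyze.

A run is described by a YAML config (seed mandatory) and produces a run
directory with per-stage outputs plus a manifest recording the config, the
seed, the package version and a SHA-256 hash of every file written, so two
runs with the same config are byte-identical and any cross-stage mutation
is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .caller import CallerConfig, build_il_genotype, call_segments, filter_and_classify
from .io import (
    read_genome_map,
    read_genotypes_abh,
    read_marker_panel,
    read_phenotypes,
    read_segments_bed,
    write_genome_map,
    write_genotypes_abh,
    write_marker_panel,
    write_phenotypes,
    write_segments_bed,
)
from .model import GenomeMap, Marker, MarkerPanel, ValidationError
from .phenotypes import call_qtls, correlation_matrix, dunnett_test, two_way_anova
from .selection import SelectionPolicy, select_final_library, select_generation
from .simulate import (
    Diplotype,
    PedigreeSpec,
    QTLEffect,
    TraitArchitecture,
    TraitModel,
    TrialDesign,
    advance_generation,
    genotype_population,
    simulate_phenotypes,
    true_segments,
)
from .stats import collection_summary, graphical_genotype

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "call", "stats", "select", "analyze")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int
    outdir: Path
    stages: tuple[str, ...] = ALL_STAGES
    options: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValidationError("config must set a seed (stochastic stages)")
        stages = tuple(raw.get("stages", ALL_STAGES))
        unknown = [s for s in stages if s not in ALL_STAGES]
        if unknown:
            raise ValidationError(f"unknown stages: {unknown}")
        outdir = Path(raw.get("outdir", "il_run"))
        options = {k: v for k, v in raw.items() if k not in ("seed", "outdir", "stages")}
        return cls(seed=int(raw["seed"]), outdir=outdir, stages=stages,
                   options=options)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "stages": list(self.stages),
            **self.options,
        }


def default_scenario_genome() -> GenomeMap:
    """A compact 5-chromosome toy genome (bp sizes in the tens of Mbp)."""
    return GenomeMap.from_lists(
        [
            ("chr01", 38_000_000, 110.0),
            ("chr02", 32_000_000, 95.0),
            ("chr03", 28_000_000, 90.0),
            ("chr04", 34_000_000, 100.0),
            ("chr05", 30_000_000, 85.0),
        ]
    )


def evenly_spaced_panel(genome: GenomeMap, spacing_bp: int) -> MarkerPanel:
    markers = []
    for chrom in genome.chromosomes:
        k = 0
        for pos in range(spacing_bp, chrom.length_bp + 1, spacing_bp):
            k += 1
            markers.append(Marker(f"{chrom.name}_m{k:04d}", chrom.name, pos))
    return MarkerPanel(tuple(markers))


def simulate_il_program(
    genome: GenomeMap,
    panel: MarkerPanel,
    pedigree: PedigreeSpec,
    policy: SelectionPolicy,
    caller_config: CallerConfig,
    rng: np.random.Generator,
) -> dict[str, Diplotype]:
    """Run a marker-assisted backcross + selfing program on true genotypes.

    Each backcross generation the candidates are genotyped (noise-free for
    selection truth), their segments called, and the greedy policy keeps
    the plants that preserve donor coverage with the fewest introgressions.
    Selfing generations then fix the selected material.  Returns the final
    generation as named diplotypes.
    """
    population = [Diplotype.f1(genome)]
    for gen in range(1, pedigree.n_backcross + 1):
        offspring = advance_generation(
            population, "backcross_to_recurrent",
            pedigree.plants_per_generation, genome, rng,
        )
        population = _select_on_truth(
            offspring, genome, panel, policy, caller_config
        )
    for gen in range(1, pedigree.n_self + 1):
        offspring = advance_generation(
            population, "self", pedigree.plants_per_generation, genome, rng
        )
        population = _select_on_truth(
            offspring, genome, panel, policy, caller_config
        )
    width = max(4, len(str(len(population))))
    return {
        f"IL{i + 1:0{width}d}": dip for i, dip in enumerate(population)
    }


def _select_on_truth(offspring, genome, panel, policy, caller_config):
    matrix = genotype_population(offspring, panel)
    ils = []
    for line_id in matrix.line_ids:
        segs = call_segments(matrix.row(line_id), panel, genome, caller_config)
        reported, _ = filter_and_classify(segs, caller_config)
        ils.append(build_il_genotype(line_id, reported, genome=genome))
    # plants that lost all donor segments cannot contribute to the library
    index = {il.line_id: i for i, il in enumerate(ils)}
    carriers = [il for il in ils if il.n_segments > 0]
    if not carriers:
        return [offspring[0]]
    outcome = select_generation(carriers, policy, genome)
    return [offspring[index[lid]] for lid in outcome.selected_ids]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in order and write a manifest.

    Re-running with the same config reproduces byte-identical outputs; the
    manifest records SHA-256 hashes of every file each stage wrote.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    ctx: dict[str, Any] = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            files = _STAGES[stage](config, out, ctx)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s wrote %d files", stage, len(files))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    opts = config.options.get("simulate", {})
    rng = np.random.default_rng(config.seed)
    genome = (
        read_genome_map(opts["genome"]) if "genome" in opts
        else default_scenario_genome()
    )
    spacing = int(opts.get("marker_spacing_bp", 500_000))
    panel = evenly_spaced_panel(genome, spacing)
    pedigree = PedigreeSpec(**opts.get("pedigree", {}))
    policy = SelectionPolicy(**opts.get("policy", {}))
    caller_cfg = CallerConfig(**config.options.get("caller", {}))
    lines = simulate_il_program(genome, panel, pedigree, policy, caller_cfg, rng)

    matrix = genotype_population(
        lines,
        panel,
        missing_rate=float(opts.get("missing_rate", 0.02)),
        error_rate=float(opts.get("error_rate", 0.002)),
        rng=rng,
    )
    truth = [
        build_il_genotype(lid, true_segments(dip, genome), pedigree.label(),
                          genome=genome)
        for lid, dip in lines.items()
    ]

    arch_opts = opts.get("architecture", {})
    qtls = tuple(QTLEffect(**q) for q in arch_opts.get("qtls", []))
    if "traits" in arch_opts:
        traits = {
            t: TraitModel(v["location_means"], v["location_sds"])
            for t, v in arch_opts["traits"].items()
        }
        arch = TraitArchitecture(
            traits, qtls,
            float(arch_opts.get("block_sd_frac", 0.02)),
            float(arch_opts.get("gxl_sd_frac", 0.0)),
        )
    else:
        from .simulate import default_trait_architecture

        arch = default_trait_architecture(
            qtls,
            float(arch_opts.get("block_sd_frac", 0.02)),
            float(arch_opts.get("gxl_sd_frac", 0.0)),
        )
    design = TrialDesign(**{
        **opts.get("design", {}),
        **({"locations": tuple(opts["design"]["locations"])}
           if "design" in opts and "locations" in opts["design"] else {}),
    })
    pheno = simulate_phenotypes(dict(zip([t.line_id for t in truth], truth)),
                                arch, design, rng)

    files = []
    write_genome_map(genome, out / "genome.tsv")
    write_marker_panel(panel, out / "panel.tsv")
    write_genotypes_abh(matrix, out / "genotypes.csv")
    write_segments_bed(truth, out / "truth_segments.bed")
    write_phenotypes(pheno, out / "phenotypes.csv")
    files = [out / f for f in
             ("genome.tsv", "panel.tsv", "genotypes.csv", "truth_segments.bed",
              "phenotypes.csv")]
    ctx.update(genome=genome, panel=panel, matrix=matrix, design=design)
    return files


def _stage_call(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    genome = ctx.get("genome") or read_genome_map(out / "genome.tsv")
    panel = ctx.get("panel") or read_marker_panel(out / "panel.tsv")
    matrix = ctx.get("matrix") or read_genotypes_abh(out / "genotypes.csv", panel)
    cfg = CallerConfig(**config.options.get("caller", {}))
    ils = []
    for line_id in matrix.line_ids:
        segs = call_segments(matrix.row(line_id), panel, genome, cfg)
        reported, _ = filter_and_classify(segs, cfg)
        ils.append(build_il_genotype(line_id, reported, genome=genome))
    write_segments_bed(ils, out / "segments.bed")
    ctx["ils"] = ils
    return [out / "segments.bed"]


def _stage_stats(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    genome = ctx.get("genome") or read_genome_map(out / "genome.tsv")
    ils = ctx.get("ils") or read_segments_bed(out / "segments.bed")
    cfg = CallerConfig(**config.options.get("caller", {}))
    het = config.options.get("stats", {}).get("count_het", True)
    report = collection_summary(ils, genome, cfg, count_het=het)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    graphical_genotype(ils, genome, out / "bands.txt")
    return [out / "report.json", out / "bands.txt"]


def _stage_select(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    genome = ctx.get("genome") or read_genome_map(out / "genome.tsv")
    ils = ctx.get("ils") or read_segments_bed(out / "segments.bed")
    final = select_final_library(ils, genome)
    (out / "selected.txt").write_text(
        "".join(f"{lid}\n" for lid in final.selected_ids)
    )
    with open(out / "gaps.bed", "w") as fh:
        fh.write("#chrom\tstart\tend\n")
        for chrom, s, e in final.gaps:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")
    return [out / "selected.txt", out / "gaps.bed"]


def _stage_analyze(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    opts = config.options.get("analyze", {})
    pheno = read_phenotypes(out / "phenotypes.csv")
    control = opts.get("control", "PS")
    alpha = float(opts.get("alpha", 0.05))
    min_loc = int(opts.get("min_locations", 2))
    traits = opts.get("traits") or sorted(pheno["trait"].unique())
    locations = sorted(pheno["location"].unique())

    files: list[Path] = []
    anova_rows = []
    qtl_rows = []
    bundle: dict[str, Any] = {"control": control, "alpha": alpha,
                              "min_locations": min_loc, "traits": {}}
    for trait in traits:
        trait_locs = sorted(
            pheno.loc[pheno["trait"] == trait, "location"].unique()
        )
        entry: dict[str, Any] = {}
        if len(trait_locs) >= 2:
            aov = two_way_anova(pheno, trait, locations=trait_locs)
            for term, row in aov.table.iterrows():
                anova_rows.append(
                    {"trait": trait, "label": aov.label, "term": term,
                     "df": row["df"], "sum_sq": row["sum_sq"],
                     "F": row["F"], "p": row["p"]}
                )
            entry["anova_label"] = aov.label
        dunnett = {}
        for loc in trait_locs:
            try:
                dunnett[loc] = dunnett_test(pheno, trait, control, location=loc)
            except ValidationError:
                continue
        for loc, res in dunnett.items():
            path = out / f"dunnett_{trait}_{loc}.csv"
            res.table.to_csv(path)
            files.append(path)
        if len(dunnett) >= 2:
            calls = call_qtls(dunnett, alpha=alpha, min_locations=min_loc)
            for c in calls:
                qtl_rows.append(
                    {"trait": trait, "il": c.il, "called": c.called,
                     "n_significant": c.n_significant,
                     "direction": c.direction, "mean_percent": c.mean_percent}
                )
            entry["n_called"] = sum(c.called for c in calls)
        bundle["traits"][trait] = entry

    import pandas as pd

    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
    pd.DataFrame(qtl_rows).to_csv(out / "qtl_calls.csv", index=False)
    files += [out / "anova.csv", out / "qtl_calls.csv"]
    for loc, corr in correlation_matrix(pheno, traits=None, alpha=0.01).items():
        path = out / f"correlations_{loc}.csv"
        corr.r.to_csv(path)
        files.append(path)
    with open(out / "analysis.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
    files.append(out / "analysis.json")
    return files


_STAGES = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "stats": _stage_stats,
    "select": _stage_select,
    "analyze": _stage_analyze,
}
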