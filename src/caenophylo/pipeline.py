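"""End-to-end orchestration of the comparative-phylogenomics stages.

A :class:`PipelineConfig` gathers every threshold used across the analyses
(single-copy presence minimum, bootstrap collapse threshold, duplication-
ratio exclusion threshold, gene-family length filter, stochastic-map count,
significance level) plus the seed and simulation parameters.  ``run``
executes the stages in dependency order on synthetic inputs, writing plain
tab-separated outputs, the resolved configuration and a log into the run
directory; a rerun with the same config and seed is bit-identical (outputs
carry no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import ancestral, genefamily, genomestats, orthology, supertree, synth
from .pgls import pgls_fit
from .synth import SimulationConfig
from .trees import parse_newick, write_newick

log = logging.getLogger("caenophylo")

STAGES = (
    "simulate",
    "orthology",
    "supertree",
    "ancestral",
    "pgls",
    "genomestats",
    "genefamily",
)


@dataclass
class PipelineConfig:
    """Resolved parameters for a pipeline run."""

    seed: int = 0
    outdir: str = "caenophylo_run"
    stages: tuple[str, ...] = STAGES
    # analysis thresholds
    min_present: int = 27
    n_species_total: int = 33
    support_threshold: int = 50
    dup_ratio_threshold: float = 1.2
    qc_presence_min: int = 22
    qc_mean_count_max: float = 1.5
    min_seq_length: int = 700
    n_maps: int = 1000
    alpha_level: float = 0.05
    supertree_mode: str = "exhaustive"
    supertree_taxa: int = 6
    n_gene_trees: int = 30
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> list[str]:
        """Non-mutating sanity report; empty list means OK."""
        problems = []
        if not 1 <= self.min_present <= self.n_species_total:
            problems.append("min_present must lie in [1, n_species_total]")
        if self.support_threshold < 0:
            problems.append("support_threshold must be >= 0")
        if self.dup_ratio_threshold <= 0:
            problems.append("dup_ratio_threshold must be positive")
        if self.n_maps < 1:
            problems.append("n_maps must be >= 1")
        if not 0 < self.alpha_level < 1:
            problems.append("alpha_level must be in (0, 1)")
        if self.supertree_mode not in ("exhaustive", "nni"):
            problems.append(f"unknown supertree mode {self.supertree_mode!r}")
        if self.supertree_mode == "exhaustive" and self.supertree_taxa > 8:
            problems.append(
                "exhaustive supertree search supports at most 8 taxa; use nni"
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            problems.append(f"unknown stages {sorted(unknown)}")
        return problems

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # the location is not a parameter of the analysis
        return json.dumps(d, indent=2, sort_keys=True, default=str)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: PipelineConfig) -> Path:
    """Execute the configured stages on synthetic inputs; returns the run
    directory."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    sim = config.simulation.replace(seed=config.seed)
    seed = config.seed

    log.info("run directory: %s", outdir)
    for name, value in (
        ("min_present", config.min_present),
        ("support_threshold", config.support_threshold),
        ("dup_ratio_threshold", config.dup_ratio_threshold),
        ("min_seq_length", config.min_seq_length),
        ("n_maps", config.n_maps),
        ("alpha_level", config.alpha_level),
    ):
        log.info("threshold %s = %s", name, value)

    # --- simulate -----------------------------------------------------------
    species_tree, _ = synth.sim_species_tree(
        sim.n_species, sim.birth_rate, seed=seed
    )
    (outdir / "species_tree.nwk").write_text(write_newick(species_tree) + "\n")
    og_table, og_truth = synth.sim_orthogroup_table(
        sorted(species_tree.leaf_labels()),
        sim.n_orthogroups,
        planted_dup_species=sorted(species_tree.leaf_labels())[:2],
        planted_dup_fraction=sim.planted_dup_fraction,
        seed=seed + 1,
    )
    og_table.write_tsv(outdir / "orthogroups.tsv")
    annotation = synth.sim_annotation_and_assembly(sim, seed=seed + 2)
    genomestats.write_gff3(annotation.annotation, outdir / "annotation.gff3")
    genomestats.write_fasta(annotation.sequences, outdir / "assembly.fasta")
    log.info("simulate: %d species, %d orthogroups", sim.n_species, sim.n_orthogroups)
    if "simulate" == config.stages[-1] or set(config.stages) == {"simulate"}:
        return outdir

    # --- orthology ----------------------------------------------------------
    if "orthology" in config.stages:
        policy = orthology.SelectionPolicy(
            n_species_total=sim.n_species,
            min_present=min(config.min_present, sim.n_species),
            support_threshold=config.support_threshold,
        )
        qc = orthology.qc_screen(
            og_table,
            presence_min=min(config.qc_presence_min, sim.n_species),
            mean_count_max=config.qc_mean_count_max,
            threshold=config.dup_ratio_threshold,
        )
        qc.write_tsv(outdir / "qc_report.tsv")
        log.info(
            "orthology: %d OGs selected for QC, excluded species: %s",
            qc.n_selected_ogs,
            ", ".join(qc.excluded_species) or "none",
        )

    # --- supertree ----------------------------------------------------------
    if "supertree" in config.stages:
        sub_tree, _ = synth.sim_species_tree(
            config.supertree_taxa, sim.birth_rate, seed=seed + 3, prefix="tx"
        )
        gene_trees = []
        for i in range(config.n_gene_trees):
            fam = synth.sim_gene_family(sub_tree, 0.0, 0.0, seed=seed + 10 + i)
            relabelled = fam.tree.copy()
            for leaf in relabelled.leaves():
                leaf.label = fam.species_map[leaf.label]
            gene_trees.append(relabelled)
        profile = supertree.build_quartet_profile(gene_trees)
        result = supertree.search_supertree(
            profile, mode=config.supertree_mode, seed=seed
        )
        (outdir / "supertree.nwk").write_text(write_newick(result.tree) + "\n")
        diag = pd.DataFrame(
            [
                {
                    "quartet": ",".join(sorted(s)),
                    "resolution": "|".join(
                        sorted("".join(sorted(p)) for p in res)
                    ),
                    "count": n,
                }
                for s, per in sorted(
                    profile.counts.items(), key=lambda kv: sorted(kv[0])
                )
                for res, n in sorted(
                    per.items(), key=lambda kv: sorted(map(sorted, kv[0]))
                )
            ]
        )
        _write(diag, outdir / "quartets.tsv")
        log.info("supertree: score %d over %d topologies", result.score, result.n_evaluated)

    # --- ancestral ----------------------------------------------------------
    if "ancestral" in config.stages:
        tips, _, _ = synth.sim_discrete_character(
            species_tree, sim.er_rate, sim.k_states, seed=seed + 4
        )
        pd.DataFrame(
            sorted(tips.items()), columns=["taxon", "state"]
        ).to_csv(outdir / "character.tsv", sep="\t", index=False)
        fit = ancestral.fit_er_rate(species_tree, tips, k=sim.k_states)
        model = ancestral.MkModel(sim.k_states, fit.alpha)
        maps = ancestral.sample_stochastic_maps(
            species_tree, tips, model, n_maps=config.n_maps, seed=seed + 5
        )
        summary = ancestral.summarize_maps(maps)
        _write(pd.DataFrame(summary.posterior.to_rows()), outdir / "node_posteriors.tsv")
        log.info(
            "ancestral: alpha_hat %.4f, %.2f expected transitions",
            fit.alpha,
            summary.n_transitions,
        )

    # --- pgls ---------------------------------------------------------------
    if "pgls" in config.stages:
        traits, _ = synth.sim_brownian_traits(
            species_tree, sim.beta, sim.sigma2, seed=seed + 6
        )
        traits.to_csv(outdir / "traits.tsv", sep="\t")
        report = pgls_fit(
            traits, "genome_size", [c for c in traits.columns if c != "genome_size"],
            species_tree,
        )
        _write(report.table(config.alpha_level), outdir / "pgls.tsv")
        log.info("pgls: %d species fitted", report.n)

    # --- genomestats --------------------------------------------------------
    if "genomestats" in config.stages:
        ann = annotation.annotation
        stats = genomestats.gene_structure_stats(ann)
        _write(stats.per_gene, outdir / "gene_structure.tsv")
        inter, mean_inter = genomestats.intergenic_distances(ann)
        _write(inter, outdir / "intergenic.tsv")
        metrics = genomestats.assembly_metrics(annotation.sequences)
        _write(pd.DataFrame([metrics.as_row()]), outdir / "assembly_metrics.tsv")
        log.info(
            "genomestats: %d genes, mean intron span %.1f bp, mean intergenic %.1f bp",
            stats.gene_count,
            stats.mean_intron_span,
            mean_inter,
        )

    # --- genefamily ---------------------------------------------------------
    if "genefamily" in config.stages:
        fam_tree, _ = synth.sim_species_tree(8, sim.birth_rate, seed=seed + 7, prefix="gf")
        fam = synth.sim_gene_family(
            fam_tree, sim.dup_rate, sim.loss_rate, seed=seed + 8,
            root_duplication=True,
        )
        if fam.empty:
            log.info("genefamily: family extinct under these rates")
        else:
            rec = genefamily.infer_duplication_nodes(fam.tree, fam.species_map)
            rows = []
            for clade in sorted(rec.duplication_clades, key=lambda c: sorted(c)):
                comp = genefamily.post_duplication_rates(rec, clade)
                for sub, mean, n in zip(comp.clades, comp.mean_paths, comp.tip_counts):
                    rows.append(
                        {
                            "duplication": ",".join(sorted(clade)),
                            "clade": ",".join(sorted(sub)),
                            "mean_root_to_tip": mean,
                            "n_tips": n,
                        }
                    )
            _write(
                pd.DataFrame(
                    rows,
                    columns=["duplication", "clade", "mean_root_to_tip", "n_tips"],
                ),
                outdir / "gene_family_rates.tsv",
            )
            log.info(
                "genefamily: %d duplication nodes inferred", len(rec.duplication_clades)
            )
    return outdir


def demo(outdir: str = "caenophylo_demo", seed: int = 0) -> Path:
    """Small end-to-end run on bundled synthetic fixtures (< 5 min, 1 CPU)."""
    config = PipelineConfig(
        seed=seed,
        outdir=outdir,
        min_present=10,
        qc_presence_min=8,
        n_maps=200,
        supertree_taxa=6,
        n_gene_trees=20,
        simulation=SimulationConfig(
            seed=seed,
            n_species=12,
            n_orthogroups=60,
            n_scaffolds=3,
            genes_per_scaffold=25,
        ),
    )
    return run(config)
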