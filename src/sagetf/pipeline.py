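"""End-to-end orchestration: simulate -> differential -> scan -> enrich -> co-factor.

The stage order mirrors the analysis funnel: differentially abundant tags
between genotypes per stage, tag-to-gene mapping and cross-stage Venn
statistics, fold-change clustering, anchor-PWM promoter scanning under
phylogenetic-footprint constraints, annotation-term enrichment of the
anchor-positive genes, and finally the anchored co-factor
over-representation analysis on the top enriched term's genes.  All
randomness flows from one root seed split per stage, so identical seed and
config reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cluster_profiles import (
    FoldChangeMatrix,
    build_matrix,
    cluster,
    stage_correlation,
)
from .cofactor import CofactorAnalysis, run_cofactor_analysis
from .enrichment import TermResult, enrich
from .motif import (
    Pwm,
    PredictedSite,
    build_pfm,
    footprint_filter,
    promoter_region,
    pwm_from_pfm,
    scan,
)
from .sage_diff import (
    DifferentialTag,
    SageLibrary,
    differential_tags,
    map_tags_to_genes,
    venn_stats,
)
from .synthetic import (
    ANCHOR_TF,
    SimulationConfig,
    Transcriptome,
    simulate_libraries,
    simulate_transcriptome,
)

logger = logging.getLogger("sagetf")

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the original error."""




@dataclass
class PipelineConfig:
    """All pipeline thresholds plus the synthetic-data configuration."""

    seed: int = 0
    alpha: float = 0.05
    rel_threshold: float = 0.80
    flank: int = 5000
    min_identity: float = 0.70
    top_fraction: float = 0.10
    window: int = 100
    z_min: float = 10.0
    fisher_max: float = 0.01
    trials: int = 1000
    bonferroni_alpha: float = 0.05
    min_genes: int = 3
    n_background: int = 500
    pseudocount: float = 0.8
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed
        self.validate()

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.rel_threshold <= 1:
            raise ValueError("rel_threshold must be in [0, 1]")
        if not 0 <= self.min_identity <= 1 or not 0 <= self.top_fraction <= 1:
            raise ValueError("conservation thresholds must be fractions")
        if self.window < 0 or self.flank < 0 or self.trials < 0:
            raise ValueError("window, flank and trials must be non-negative")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class PipelineResult:
    config: PipelineConfig
    transcriptome: Transcriptome
    libraries: list
    diff_by_stage: dict[str, list[DifferentialTag]]
    gene_sets_by_stage: dict[str, set[str]]
    folds_by_stage: dict[str, dict[str, float]]
    venn: object
    matrix: FoldChangeMatrix
    correlations: list
    anchor_sites_by_gene: dict[str, list[PredictedSite]]
    anchor_positive: list[str]
    enrichment: list[TermResult]
    target_genes: list[str]
    cofactor: CofactorAnalysis | None
    funnel: dict[str, int]


def _stage_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _gene_folds(
    diffs: Sequence[DifferentialTag], tag_index: Mapping[str, Sequence[str]]
) -> tuple[set[str], dict[str, float]]:
    """Gene set and per-gene fold (most significant tag wins) for one stage."""
    mapping = map_tags_to_genes([d.tag for d in diffs], tag_index)
    best: dict[str, DifferentialTag] = {}
    for d in diffs:
        for gene in mapping.mapped.get(d.tag, ()):
            if gene not in best or d.p_value < best[gene].p_value:
                best[gene] = d
    return set(best), {g: d.fold_change for g, d in best.items()}


def _scan_gene(
    pwms: Sequence[Pwm],
    transcriptome: Transcriptome,
    gene_id: str,
    config: PipelineConfig,
) -> dict[str, list[PredictedSite]]:
    gene = transcriptome.gene(gene_id)
    start, end = promoter_region(gene.tss, config.flank)
    end = min(end, len(gene.promoter))
    seq = gene.promoter[start:end]
    track = transcriptome.conservation.get(gene_id, [])
    out: dict[str, list[PredictedSite]] = {}
    for pwm in pwms:
        sites = scan(pwm, seq, rel_threshold=config.rel_threshold, gene_id=gene_id)
        if start:
            sites = [dataclasses.replace(s, start=s.start + start, end=s.end + start) for s in sites]
        out[pwm.tf_id] = footprint_filter(
            sites,
            track,
            min_identity=config.min_identity,
            top_fraction=config.top_fraction,
            total_length=len(gene.promoter),
        )
    return out


def run(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the full pipeline into a run directory.

    Writes every intermediate table (tag tables, differential TSVs, Venn
    JSON, fold matrix, dendrograms, PFMs, site BEDs, enrichment and
    co-factor TSVs) plus a provenance manifest with the per-stage gene
    funnel.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}
    sim = config.simulation
    stage_name = "configure"
    try:
        return _run_stages(config, outdir, funnel, sim, _note := [stage_name])
    except PipelineError:
        raise
    except Exception as exc:  # halt with the failing stage's name
        raise PipelineError(f"stage {_note[0]!r} failed: {exc}") from exc


def _run_stages(
    config: PipelineConfig,
    outdir: Path,
    funnel: dict[str, int],
    sim: SimulationConfig,
    stage_note: list[str],
) -> "PipelineResult":

    # --- stage 1: synthetic inputs -------------------------------------
    stage_note[0] = "simulate"
    logger.info("simulating transcriptome and libraries (seed=%d)", config.seed)
    transcriptome, truth = simulate_transcriptome(sim)
    libraries = simulate_libraries(transcriptome, sim)
    funnel["genes_simulated"] = sim.n_genes
    sio.write_fasta(transcriptome.promoters(), outdir / "promoters.fa")
    sio.write_fasta(transcriptome.transcripts(), outdir / "transcripts.fa")
    sio.write_conservation_bed(transcriptome.conservation, outdir / "conservation.bed")
    sio.write_annotations(transcriptome.annotations, outdir / "annotations.tsv")
    for tf, sites in transcriptome.tf_sites.items():
        sio.write_fasta(
            {f"{tf}_site{i + 1}": s for i, s in enumerate(sites)},
            outdir / f"sites_{tf}.fa",
        )
    for simlib in libraries:
        sio.write_tag_table(
            simlib.raw_records, outdir / f"tags_{simlib.library.id}.tsv"
        )
    sio.write_json(
        {
            "de_genes": {g: list(v) for g, v in sorted(truth.de_genes.items())},
            "enriched_term": truth.enriched_term,
            "enriched_term_genes": sorted(truth.enriched_term_genes),
            "anchor_genes": sorted(truth.anchor_genes),
            "target_genes": truth.target_genes,
            "cofactor_genes": sorted(truth.cofactor_genes),
            "planted_sites": [
                dataclasses.asdict(s) for s in truth.planted_sites
            ],
        },
        outdir / "ground_truth.json",
    )

    # --- stage 2: differential tags per stage --------------------------
    stage_note[0] = "difftags"
    by_id = {l.library.id: l.library for l in libraries}
    tag_index = transcriptome.tag_index()
    diff_by_stage: dict[str, list[DifferentialTag]] = {}
    gene_sets: dict[str, set[str]] = {}
    folds_by_stage: dict[str, dict[str, float]] = {}
    for stage in sim.stage_labels:
        wt, mut = by_id[f"Wt_{stage}"], by_id[f"mutant_{stage}"]
        diffs = differential_tags(wt, mut, alpha=config.alpha)
        diff_by_stage[stage] = diffs
        genes, folds = _gene_folds(diffs, tag_index)
        gene_sets[stage] = genes
        folds_by_stage[stage] = folds
        logger.info("stage %s: %d differential tags, %d genes", stage, len(diffs), len(genes))
        mapping = map_tags_to_genes([d.tag for d in diffs], tag_index)
        pd.DataFrame(
            [
                {
                    "tag": d.tag,
                    "wt_count": d.count_a,
                    "mut_count": d.count_b,
                    "p_value": d.p_value,
                    "fold_change": d.fold_change,
                    "direction": d.direction,
                    "gene_ids": ",".join(mapping.mapped.get(d.tag, [])),
                }
                for d in diffs
            ]
        ).to_csv(outdir / f"difftags_{stage}.tsv", sep="\t", index=False)
    diff_genes = sorted(set().union(*gene_sets.values()))
    funnel["differential_genes"] = len(diff_genes)

    # --- stage 3: cross-stage overlap ----------------------------------
    stage_note[0] = "venn"
    stages = sim.stage_labels
    venn = None
    if len(stages) == 3:
        venn = venn_stats(
            gene_sets[stages[0]], gene_sets[stages[1]], gene_sets[stages[2]],
            labels=tuple(stages),
        )
        sio.write_json(venn.to_dict(), outdir / "venn.json")

    # --- stage 4: clustering and stage correlations --------------------
    stage_note[0] = "cluster"
    matrix = build_matrix(folds_by_stage, genes=diff_genes)
    sio.write_fold_matrix(matrix, outdir / "fold_matrix.tsv")
    correlations = []
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            correlations.append(stage_correlation(matrix, stages[i], stages[j]))
    sio.write_json(
        [
            {
                "stage_a": c.stage_a,
                "stage_b": c.stage_b,
                "n_valid": c.n_valid,
                "rho": None if np.isnan(c.rho) else c.rho,
                "p_value": None if np.isnan(c.p_value) else c.p_value,
            }
            for c in correlations
        ],
        outdir / "stage_correlations.json",
    )
    if len(diff_genes) >= 2:
        (outdir / "gene_dendrogram.nwk").write_text(
            cluster(matrix, axis="genes").to_newick() + "\n"
        )
    if len(stages) >= 2:
        (outdir / "stage_dendrogram.nwk").write_text(
            cluster(matrix, axis="stages").to_newick() + "\n"
        )

    # --- stage 5: binding profiles -------------------------------------
    stage_note[0] = "pwm"
    pwms: list[Pwm] = []
    for tf, site_seqs in sorted(transcriptome.tf_sites.items()):
        pfm = build_pfm(site_seqs)
        sio.write_pfm(pfm, outdir / f"pfm_{tf}.txt", name=tf)
        pwms.append(pwm_from_pfm(pfm, pseudocount=config.pseudocount, tf_id=tf))
    pwm_by_tf = {p.tf_id: p for p in pwms}

    # --- stage 6: anchor scan + footprint filter over differential genes
    stage_note[0] = "scan+footprint"
    anchor_pwm = pwm_by_tf[ANCHOR_TF]
    anchor_sites_by_gene: dict[str, list[PredictedSite]] = {}
    for gene_id in diff_genes:
        sites = _scan_gene([anchor_pwm], transcriptome, gene_id, config)
        anchor_sites_by_gene[gene_id] = sites[ANCHOR_TF]
    anchor_positive = sorted(
        g for g, s in anchor_sites_by_gene.items() if s
    )
    funnel["anchor_positive_genes"] = len(anchor_positive)
    sio.write_sites_bed(
        [s for sites in anchor_sites_by_gene.values() for s in sites],
        outdir / "anchor_sites.bed",
    )

    # --- stage 7: term enrichment of anchor-positive genes -------------
    stage_note[0] = "enrich"
    enrichment = enrich(
        anchor_positive,
        transcriptome.annotations,
        alpha=config.bonferroni_alpha,
        min_genes=config.min_genes,
    )
    pd.DataFrame(
        [
            {
                "term": r.term,
                "genes_in_list": r.k,
                "list_size": r.n,
                "genes_in_background": r.K,
                "background_size": r.N,
                "ease_p": r.ease_p,
                "bonferroni_p": r.bonferroni_p,
            }
            for r in enrichment
        ]
    ).to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
    if enrichment:
        top = enrichment[0]
        target_genes = sorted(top.genes & set(anchor_positive))
    else:
        logger.warning("no enriched term; co-factor stage uses all anchor-positive genes")
        target_genes = list(anchor_positive)
    funnel["enriched_term_target_genes"] = len(target_genes)
    sio.write_gene_list(target_genes, outdir / "target_genes.txt")

    # --- stage 8: anchored co-factor over-representation ---------------
    stage_note[0] = "cofactor"
    cofactor = None
    if target_genes and len(anchor_positive) > len(target_genes):
        rng = _stage_rng(config.seed, 8)
        pool = anchor_positive
        non_targets = sorted(set(g.gene_id for g in transcriptome.genes) - set(target_genes))
        n_bg = min(config.n_background, len(non_targets))
        background = sorted(rng.choice(non_targets, size=n_bg, replace=False).tolist())
        scan_genes = sorted(set(pool) | set(background))
        gene_sites = {
            g: _scan_gene(pwms, transcriptome, g, config) for g in scan_genes
        }
        sio.write_sites_bed(
            [
                s
                for sites in gene_sites.values()
                for tf_sites in sites.values()
                for s in tf_sites
            ],
            outdir / "all_sites.bed",
        )
        cof_seed = int(
            np.random.SeedSequence([config.seed, 9]).generate_state(1)[0] % (2**31)
        )
        cofactor = run_cofactor_analysis(
            target_genes,
            pool,
            background,
            gene_sites,
            anchor_tf=ANCHOR_TF,
            window=config.window,
            z_min=config.z_min,
            fisher_max=config.fisher_max,
            trials=config.trials,
            seed=cof_seed,
        )
        pd.DataFrame([r.to_row() for r in cofactor.results]).to_csv(
            outdir / "cofactor_results.tsv", sep="\t", index=False
        )
        if cofactor.null is not None:
            sio.write_json(
                {
                    "n_trials": cofactor.null.n_trials,
                    "z": {tf: list(v) for tf, v in cofactor.null.z.items()},
                    "fisher": {tf: list(v) for tf, v in cofactor.null.fisher.items()},
                },
                outdir / "cofactor_null.json",
            )
        funnel["enriched_cofactors"] = len(cofactor.enriched)
    else:
        logger.warning("co-factor stage skipped: empty target set or pool")

    manifest = {
        "seed": config.seed,
        "funnel": funnel,
        "config": dataclasses.asdict(config),
        "stages": [
            "simulate", "filter", "difftags", "venn", "cluster",
            "pwm", "scan", "footprint", "enrich", "cofactor",
        ],
    }
    sio.write_json(manifest, outdir / "manifest.json")
    return PipelineResult(
        config=config,
        transcriptome=transcriptome,
        libraries=libraries,
        diff_by_stage=diff_by_stage,
        gene_sets_by_stage=gene_sets,
        folds_by_stage=folds_by_stage,
        venn=venn,
        matrix=matrix,
        correlations=correlations,
        anchor_sites_by_gene=anchor_sites_by_gene,
        anchor_positive=anchor_positive,
        enrichment=enrichment,
        target_genes=target_genes,
        cofactor=cofactor,
        funnel=funnel,
    )
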