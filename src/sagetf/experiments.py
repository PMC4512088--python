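"""Calibration and recovery experiments on synthetic data.

Each function here runs one self-contained computational experiment --
exact-test oracle agreement, null calibration, spike-in recovery, motif
recovery, footprint retention, and the anchored co-factor analysis on
planted or null promoters -- and returns plain numbers.  The test suite
asserts on these numbers and the acceptance script reports them, so the
experiment definitions (configurations, sizes, statistics) live in exactly
one place.

The Audic-Claverie and hypergeometric oracles in this module deliberately
avoid the implementation path used by the package (scipy's distribution
tails): they sum the underlying series term by term in log space.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.stats import kstest

from . import sage_diff as sd
from .cofactor import CofactorAnalysis, run_cofactor_analysis
from .motif import ConservedRegion, PredictedSite, discover_motif, footprint_filter
from .pipeline import PipelineConfig, _scan_gene
from .enrichment import ease_p, fisher_p
from .synthetic import (
    ANCHOR_TF,
    COFACTOR_TF,
    SimulationConfig,
    simulate_libraries,
    simulate_transcriptome,
)

__all__ = [
    "ac_lower_tail_oracle",
    "ac_oracle_max_rel_err",
    "null_type1_experiment",
    "recovery_experiment",
    "motif_recovery_experiment",
    "footprint_retention_experiment",
    "ease_oracle_experiment",
    "cofactor_experiment",
    "empirical_null_uniformity",
]


# ---------------------------------------------------------------------------
# exact-test oracle


def ac_lower_tail_oracle(x: int, y: int, n1: float, n2: float) -> float:
    """P(Y <= y | x) by direct term-by-term summation of the conditional pmf."""
    total = 0.0
    log_ratio = math.log(n2) - math.log(n1)
    log_denom = math.log1p(n2 / n1)
    for k in range(y + 1):
        total += math.exp(
            k * log_ratio
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * log_denom
        )
    return total


def ac_oracle_max_rel_err(
    max_count: int = 50,
    size_pairs: Sequence[tuple[float, float]] = ((1e3, 1e3), (1e3, 1e4), (1e5, 1e3)),
) -> float:
    """Worst relative disagreement between the exact test and its series oracle.

    Covers every x, y <= max_count at the given library-size pairs, for the
    symmetrised two-sided p-value.
    """
    worst = 0.0
    for n1, n2 in size_pairs:
        for x in range(max_count + 1):
            for y in range(max_count + 1):
                p = sd.audic_claverie_p(x, y, n1, n2)
                oracle = min(
                    ac_lower_tail_oracle(x, y, n1, n2),
                    ac_lower_tail_oracle(y, x, n2, n1),
                )
                oracle = min(1.0, 2.0 * oracle)
                worst = max(worst, abs(p - oracle) / oracle)
    return worst


# ---------------------------------------------------------------------------
# differential-test calibration and recovery


def _null_config(seed: int) -> SimulationConfig:
    # Poisson counts (the sampling model under which the exact test is
    # calibrated), moderate-to-high expression so discreteness is mild, and
    # no noise singletons (depth-1 tags are never significant)
    return SimulationConfig(
        seed=seed,
        n_genes=1500,
        library_depth=60_000,
        de_fraction=0.0,
        promoter_length=501,
        n_stages=1,
        noise_model="poisson",
        expression_sigma=0.5,
        singleton_fraction=0.0,
        contaminant_fraction=0.0,
    )


def null_type1_experiment(seed: int = 11, alpha: float = 0.05):
    """Type-I error of the differential screen on a null simulation.

    Returns (rejection_rate, n_expressed_tags).  The binomial 3-SD band
    around alpha is the acceptance envelope.
    """
    cfg = _null_config(seed)
    transcriptome, _ = simulate_transcriptome(cfg)
    libs = simulate_libraries(transcriptome, cfg)
    wt = next(l for l in libs if l.library.genotype == "Wt").library
    mut = next(l for l in libs if l.library.genotype == "mutant").library
    n1, n2 = wt.total_useful, mut.total_useful
    tags = set(wt.tags) | set(mut.tags)
    flagged = sum(
        sd.audic_claverie_p(wt.tags.get(t, 0), mut.tags.get(t, 0), n1, n2) < alpha
        for t in tags
    )
    return flagged / len(tags), len(tags)


def recovery_experiment(seeds: Sequence[int] = tuple(range(10)), min_mean: float = 20.0):
    """Pooled recovery of spiked >= 4-fold genes at expected count >= min_mean.

    Returns (recovered, eligible) pooled over the seeds; each seed simulates
    one wild-type/mutant pair under Poisson noise and runs the differential
    screen at alpha = 0.05.
    """
    recovered = eligible = 0
    for seed in seeds:
        cfg = SimulationConfig(
            seed=seed,
            n_genes=300,
            library_depth=6000,
            de_fraction=0.3,
            de_fold=4.0,
            promoter_length=501,
            n_stages=1,
            noise_model="poisson",
            singleton_fraction=0.0,
            contaminant_fraction=0.0,
        )
        transcriptome, truth = simulate_transcriptome(cfg)
        libs = simulate_libraries(transcriptome, cfg)
        wt = next(l for l in libs if l.library.genotype == "Wt").library
        mut = next(l for l in libs if l.library.genotype == "mutant").library
        index = transcriptome.tag_index()
        flagged = {
            g
            for d in sd.differential_tags(wt, mut)
            for g in index.get(d.tag, [])
        }
        for gene_id in truth.de_genes:
            if transcriptome.gene(gene_id).baseline_mean >= min_mean:
                eligible += 1
                recovered += gene_id in flagged
    return recovered, eligible


# ---------------------------------------------------------------------------
# motif discovery and footprinting


def motif_recovery_experiment(
    seeds: Sequence[int] = tuple(range(10)),
    consensus: str = "AAGTCAAAGTCA",
    n_sequences: int = 10,
):
    """Per-seed count of planted offsets recovered by motif discovery."""
    hits_per_seed = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        seqs, offsets = [], []
        for _ in range(n_sequences):
            left = int(rng.integers(20, 80))
            flanks = rng.choice(list("ACGT"), size=left + 40)
            seqs.append(
                "".join(flanks[:left]) + consensus + "".join(flanks[left:])
            )
            offsets.append(left)
        res = discover_motif(seqs, width=len(consensus), seed=seed)
        hits_per_seed.append(
            sum(o == t for o, t in zip(res.offsets, offsets))
        )
    return hits_per_seed


def footprint_retention_experiment(n_genes: int = 10, seed: int = 0):
    """Planted-vs-decoy retention on a constructed conservation track.

    Each promoter carries planted sites inside a 0.9-identity block and
    decoy sites inside a 0.5-identity block; returns (planted_retained,
    planted_total, decoys_retained).
    """
    rng = np.random.default_rng(seed)
    planted_kept = planted_total = decoys_kept = 0
    for g in range(n_genes):
        length = 10_000
        a_start = int(rng.integers(0, 4000))
        b_start = int(rng.integers(5000, 9000))
        regions = [
            ConservedRegion(a_start, a_start + 500, 0.9),
            ConservedRegion(b_start, b_start + 500, 0.5),
        ]
        sites = []
        for k in range(2):
            s = a_start + 50 + 150 * k
            sites.append(PredictedSite("TF", f"g{g}", s, s + 12, "+", 1.0, 0.9))
        planted = list(sites)
        for k in range(2):
            s = b_start + 50 + 150 * k
            sites.append(PredictedSite("TF", f"g{g}", s, s + 12, "+", 1.0, 0.9))
        kept = footprint_filter(
            sites, regions, min_identity=0.70, top_fraction=0.10,
            total_length=length,
        )
        planted_total += len(planted)
        planted_kept += sum(s in planted for s in kept)
        decoys_kept += sum(s not in planted for s in kept)
    return planted_kept, planted_total, decoys_kept


def ease_oracle_experiment(max_n: int = 12, N: int = 40):
    """EASE vs plain-Fisher ordering and enumeration-oracle agreement.

    Exhausts all consistent (k, n, K) tables at universe size N up to list
    size max_n.  Returns (n_tables, violations, max_rel_err).
    """

    def tail(kmin, n, K):
        if kmin <= 0:
            return 1.0
        total = sum(
            math.comb(K, k) * math.comb(N - K, n - k)
            for k in range(kmin, min(n, K) + 1)
        )
        return total / math.comb(N, n)

    tables = violations = 0
    worst = 0.0
    for n in range(1, max_n + 1):
        for K in range(1, N + 1):
            for k in range(1, min(n, K) + 1):
                tables += 1
                e = ease_p(k, n, K, N)
                f = fisher_p(k, n, K, N)
                if e < f - 1e-12:
                    violations += 1
                worst = max(worst, abs(e - tail(k - 1, n, K)) / tail(k - 1, n, K))
    return tables, violations, worst


# ---------------------------------------------------------------------------
# anchored co-factor analysis on planted / null promoters


def _cofactor_world(seed: int, planted: bool, n_genes: int = 600):
    sim = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        library_depth=4 * n_genes,
        promoter_length=1501,
        footprint_block_length=400,
        enriched_term_size=25,
        planted_cofactor_fraction=0.8 if planted else 0.0,
    )
    cfg = PipelineConfig(seed=seed, flank=750, trials=0, simulation=sim)
    transcriptome, truth = simulate_transcriptome(sim)
    return cfg, transcriptome, truth


def cofactor_experiment(
    seed: int,
    planted: bool = True,
    n_genes: int = 600,
    n_background: int = 150,
    trials: int = 200,
) -> CofactorAnalysis:
    """Scan promoters, footprint-filter, and run the co-factor analysis.

    Targets are the ground-truth target genes (differentially spiked,
    anchored, enriched-term members); the candidate pool is every anchored
    gene and the background is a seeded random draw of non-target genes.
    """
    cfg, transcriptome, truth = _cofactor_world(seed, planted, n_genes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    targets = truth.target_genes
    pool = sorted(truth.anchor_genes)
    all_genes = [g.gene_id for g in transcriptome.genes]
    non_targets = sorted(set(all_genes) - set(targets))
    background = sorted(
        rng.choice(non_targets, size=min(n_background, len(non_targets)), replace=False)
    )
    pwms = []
    from .motif import build_pfm, pwm_from_pfm

    for tf, site_seqs in sorted(transcriptome.tf_sites.items()):
        pwms.append(pwm_from_pfm(build_pfm(site_seqs), tf_id=tf))
    gene_sites = {
        g: _scan_gene(pwms, transcriptome, g, cfg)
        for g in sorted(set(pool) | set(background))
    }
    return run_cofactor_analysis(
        targets,
        pool,
        background,
        gene_sites,
        anchor_tf=ANCHOR_TF,
        window=cfg.window,
        z_min=cfg.z_min,
        fisher_max=cfg.fisher_max,
        trials=trials,
        seed=seed + 1,
    )


def empirical_null_uniformity(
    seed: int = 0,
    n_analyses: int = 50,
    target_size: int = 15,
    trials: int = 200,
    n_genes: int = 400,
    tf: str = "DECOY1",
):
    """Distribution of empirical p-values over random target sets under the null.

    One null simulation (no planted co-factor); each analysis draws a random
    target set from the anchored-gene pool, so its scores are exchangeable
    with the trial sets and the reported n/N values should be uniform.
    Returns (ks_statistic, ks_pvalue, p_values) for the Z-based empirical p
    of the given decoy TF.
    """
    cfg, transcriptome, truth = _cofactor_world(seed, planted=False, n_genes=n_genes)
    from .motif import build_pfm, pwm_from_pfm

    pwms = [
        pwm_from_pfm(build_pfm(site_seqs), tf_id=t)
        for t, site_seqs in sorted(transcriptome.tf_sites.items())
    ]
    pool = sorted(truth.anchor_genes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    # background drawn from the anchored pool as well: under the null every
    # gene set is exchangeable, and anchored genes carry the searchable
    # sequence the rate statistics need
    background = sorted(rng.choice(pool, size=min(100, len(pool)), replace=False))
    gene_sites = {
        g: _scan_gene(pwms, transcriptome, g, cfg)
        for g in sorted(set(pool) | set(background))
    }
    p_values = []
    for i in range(n_analyses):
        targets = sorted(rng.choice(pool, size=target_size, replace=False))
        analysis = run_cofactor_analysis(
            targets,
            pool,
            background,
            gene_sites,
            anchor_tf=ANCHOR_TF,
            trials=trials,
            seed=int(rng.integers(2**31)),
        )
        result = next(r for r in analysis.results if r.tf_id == tf)
        p_values.append(result.empirical_p_z.value)
    ks = kstest(p_values, "uniform")
    return float(ks.statistic), float(ks.pvalue), p_values
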