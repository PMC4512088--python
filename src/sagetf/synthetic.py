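"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the study design end to end: two genotypes (wild
type and mutant) sampled at three embryonic stages as LongSAGE tag
libraries; promoters of +/-5 kb around a central TSS carrying planted
anchor-TF binding sites inside high-identity conserved blocks; a co-factor
motif planted within 100 bp of anchors on a designated target subset; decoy
TF sites scattered through conserved sequence; and an annotation table with
one term enriched for the target genes.

Defaults preserve the study's per-tag count spectrum at a tractable scale:
the real libraries average ~3.3 useful tags per tag type (~83,000 tags over
~25,000 types, ~18 % singletons), so the default 2,000 genes are paired with
~8,000 useful tags per library.  Counts are overdispersed (negative binomial,
dispersion 0.1) with a 5 % spiked differentially-expressed fraction at
four-fold, and promoters are 10,001 bp (TSS +/- 5 kb).  Every draw flows
from one root seed, so identical seed + config gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import sage_diff
from .motif import ConservedRegion
from .enrichment import AnnotationTable
from .sage_diff import SageLibrary, TagRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GeneModel",
    "Transcriptome",
    "SimulatedLibrary",
    "PlantedSite",
    "simulate_transcriptome",
    "simulate_libraries",
    "LINKER_TAGS",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

# artefact linker-derived tags removed by filtering (fixed synthetic linkers)
LINKER_TAGS = frozenset(
    {
        "CATGTCGGATCCTAACGATGT",
        "CATGAGGCTTAGCTTGACTAC",
    }
)

ANCHOR_TF = "NR2E1"
COFACTOR_TF = "COFACTOR"
ENRICHED_TERM = "GO:NSD"  # nervous-system-development-like term


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int = 0
    n_genes: int = 2000
    n_stages: int = 3
    library_depth: int = 8000
    de_fraction: float = 0.05
    de_fold: float = 4.0
    promoter_length: int = 10_001
    anchor_motif: str = "AAGTCAAAGTCA"
    cofactor_motif: str = "AACAATGCATTG"
    n_decoy_tfs: int = 6
    anchor_fraction: float = 0.7
    planted_cofactor_fraction: float = 0.8
    background_cofactor_fraction: float = 0.05
    decoy_site_rate: float = 0.5  # mean planted decoy sites per promoter per TF
    conserved_fraction: float = 0.20
    noise_model: str = "nb"  # "nb" (dispersion) or "poisson"
    dispersion: float = 0.1
    singleton_fraction: float = 0.18
    contaminant_fraction: float = 0.02
    expression_sigma: float = 1.25
    n_terms: int = 25
    enriched_term_size: int = 40
    enriched_term_purity: float = 0.8
    footprint_block_length: int = 600
    footprint_identity: float = 0.90
    n_anchor_sites: int = 3  # per-promoter anchor count drawn uniformly in 1..n

    def validate(self) -> None:
        fracs = {
            "de_fraction": self.de_fraction,
            "anchor_fraction": self.anchor_fraction,
            "planted_cofactor_fraction": self.planted_cofactor_fraction,
            "background_cofactor_fraction": self.background_cofactor_fraction,
            "conserved_fraction": self.conserved_fraction,
            "singleton_fraction": self.singleton_fraction,
            "enriched_term_purity": self.enriched_term_purity,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.promoter_length % 2 == 0:
            raise ValueError("promoter_length must be odd (central TSS)")
        longest = max(len(self.anchor_motif), len(self.cofactor_motif))
        if self.promoter_length < longest:
            raise ValueError("promoter_length shorter than the longest motif")
        if self.noise_model not in ("nb", "poisson"):
            raise ValueError("noise_model must be 'nb' or 'poisson'")
        if self.de_fold < 1.0:
            raise ValueError("de_fold must be >= 1")

    @property
    def stage_labels(self) -> list[str]:
        if self.n_stages == 3:
            return ["E13.5", "E15.5", "E17.5"]
        return [f"S{i + 1}" for i in range(self.n_stages)]

    @property
    def tf_ids(self) -> list[str]:
        return [ANCHOR_TF, COFACTOR_TF] + [
            f"DECOY{i + 1}" for i in range(self.n_decoy_tfs)
        ]


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    tf_id: str
    start: int
    strand: str


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    de_genes: dict[str, tuple[str, float]]  # gene -> (direction, fold)
    planted_sites: list[PlantedSite]
    enriched_term: str
    enriched_term_genes: set[str]
    anchor_genes: set[str]
    target_genes: list[str]  # enriched-term members that are DE and anchored
    cofactor_genes: set[str]  # targets that received a proximal co-factor site


@dataclass
class GeneModel:
    gene_id: str
    transcript: str
    promoter: str
    tss: int
    baseline_mean: float  # expected wild-type useful-tag count per library
    is_de: bool = False
    de_direction: str = ""  # "up"/"down" in the mutant
    de_fold: float = 1.0

    @property
    def tag(self) -> str | None:
        return sage_diff.extract_canonical_tag(self.transcript)

    def mutant_mean(self) -> float:
        if not self.is_de:
            return self.baseline_mean
        if self.de_direction == "up":
            return self.baseline_mean * self.de_fold
        return self.baseline_mean / self.de_fold


@dataclass
class Transcriptome:
    config: SimulationConfig
    genes: list[GeneModel]
    conservation: dict[str, list[ConservedRegion]]
    annotations: AnnotationTable
    tf_sites: dict[str, list[str]]  # tf -> literature-style site sequences
    ground_truth: GroundTruth

    def promoters(self) -> dict[str, str]:
        return {g.gene_id: g.promoter for g in self.genes}

    def transcripts(self) -> dict[str, str]:
        return {g.gene_id: g.transcript for g in self.genes}

    def tag_index(self) -> dict[str, list[str]]:
        return sage_diff.build_tag_index(self.transcripts())

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


@dataclass
class SimulatedLibrary:
    """One library: raw records plus the filtered SageLibrary."""

    raw_records: list[TagRecord]
    library: SageLibrary
    filter_result: sage_diff.FilterResult


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _place_blocks(
    rng: np.random.Generator,
    length: int,
    sizes: list[int],
    occupied: list[tuple[int, int]],
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals of the given sizes, greedy with retry."""
    placed: list[tuple[int, int]] = []
    for size in sizes:
        for _ in range(max_tries):
            start = int(rng.integers(0, max(1, length - size)))
            iv = (start, start + size)
            if all(iv[1] <= s or e <= iv[0] for s, e in occupied + placed):
                placed.append(iv)
                break
    return placed


def _site_set(rng: np.random.Generator, consensus: str, n_sites: int = 9) -> list[str]:
    """Literature-style site collection: consensus plus a few single-base variants.

    At most floor((n_sites - 1) / 2) sequences are mutated at one position
    each (distinct positions), so the per-column majority stays the
    consensus and its relative PWM score stays 1.0.
    """
    sites = [consensus] * n_sites
    n_mut = min((n_sites - 1) // 2, len(consensus))
    positions = rng.choice(len(consensus), size=n_mut, replace=False)
    for i, pos in enumerate(positions):
        base = consensus[pos]
        alt = rng.choice([b for b in "ACGT" if b != base])
        sites[i + 1] = consensus[:pos] + str(alt) + consensus[pos + 1 :]
    return sites


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[Transcriptome, GroundTruth]:
    """Generate gene models, promoters, conservation tracks and annotations.

    Every gene's transcript contains an NlaIII site (CATG) with a unique
    17-bp tail, so each gene maps to a unique canonical LongSAGE tag.
    Planted motif instances are exact consensus copies (or their reverse
    complements) and never overlap each other; they sit inside the
    high-identity footprint block of each anchored promoter so that they
    survive conservation filtering at the default thresholds.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    # expression weights and spiked differential genes
    weights = rng.lognormal(0.0, config.expression_sigma, n)
    weights /= weights.sum()
    means = weights * config.library_depth
    n_de = round(config.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    de_dirs = rng.choice(["up", "down"], size=n_de)

    # unique canonical tags
    tails: set[bytes] = set()
    transcripts = []
    for _ in range(n):
        while True:
            tail = _random_seq(rng, 17).tobytes()
            if tail not in tails:
                tails.add(tail)
                break
        body = _random_seq(rng, 120).tobytes()
        transcripts.append((b"ATG" + body + b"CATG" + tail).decode())

    anchor_n = round(config.anchor_fraction * n)
    anchor_idx = set(
        rng.choice(n, size=anchor_n, replace=False).tolist() if anchor_n else []
    )

    de_set = {gene_ids[i] for i in de_idx}
    anchor_genes = {gene_ids[i] for i in sorted(anchor_idx)}
    de_anchor = sorted(de_set & anchor_genes)

    # enriched annotation term drawn mostly from DE+anchored genes; the pure
    # members are the best-expressed ones so the term is enriched among the
    # genes the differential screen can actually detect
    term_size = min(config.enriched_term_size, n)
    n_pure = min(len(de_anchor), round(config.enriched_term_purity * term_size))
    mean_of = dict(zip(gene_ids, means))
    de_anchor_by_expr = sorted(de_anchor, key=lambda g: -mean_of[g])
    pure = de_anchor_by_expr[:n_pure]
    others = sorted(set(gene_ids) - set(pure))
    n_rest = min(term_size - n_pure, len(others))
    rest = list(rng.choice(others, size=n_rest, replace=False)) if n_rest else []
    enriched_members = set(map(str, pure + rest))

    target_genes = sorted(enriched_members & de_set & anchor_genes)
    n_cof = round(config.planted_cofactor_fraction * len(target_genes))
    cofactor_genes = (
        set(map(str, rng.choice(target_genes, size=n_cof, replace=False)))
        if n_cof
        else set()
    )
    # nonspecific co-factor occurrences on non-target anchored promoters
    bg_candidates = sorted(anchor_genes - set(target_genes))
    if config.planted_cofactor_fraction > 0 and bg_candidates:
        n_bg = round(config.background_cofactor_fraction * len(bg_candidates))
        bg_cof = (
            set(map(str, rng.choice(bg_candidates, size=n_bg, replace=False)))
            if n_bg
            else set()
        )
    else:
        bg_cof = set()

    decoys = [f"DECOY{i + 1}" for i in range(config.n_decoy_tfs)]
    decoy_consensus = {
        tf: _random_seq(rng, len(config.anchor_motif)).tobytes().decode()
        for tf in decoys
    }
    tf_sites = {
        ANCHOR_TF: _site_set(rng, config.anchor_motif),
        COFACTOR_TF: _site_set(rng, config.cofactor_motif),
    }
    for tf in decoys:
        tf_sites[tf] = _site_set(rng, decoy_consensus[tf])

    L = config.promoter_length
    tss = L // 2
    genes: list[GeneModel] = []
    conservation: dict[str, list[ConservedRegion]] = {}
    planted: list[PlantedSite] = []
    fb_len = min(config.footprint_block_length, L)

    for i, gene_id in enumerate(gene_ids):
        promoter = _random_seq(rng, L)
        occupied: list[tuple[int, int]] = []
        regions: list[ConservedRegion] = []

        # conserved blocks: one high-identity footprint block plus filler
        if config.conserved_fraction >= 1.0:
            fp = (0, L)
            regions.append(ConservedRegion(0, L, config.footprint_identity))
        else:
            budget = int(config.conserved_fraction * L)
            this_fb = min(fb_len, budget) if budget else 0
            fp = None
            if this_fb >= len(config.anchor_motif):
                placed = _place_blocks(rng, L, [this_fb], [])
                if placed:
                    fp = placed[0]
                    regions.append(
                        ConservedRegion(fp[0], fp[1], config.footprint_identity)
                    )
            remaining = budget - (fp[1] - fp[0] if fp else 0)
            filler_sizes = []
            while remaining >= 150:
                size = int(min(remaining, rng.integers(150, 400)))
                filler_sizes.append(size)
                remaining -= size
            for s, e in _place_blocks(
                rng, L, filler_sizes, [fp] if fp else []
            ):
                regions.append(
                    ConservedRegion(s, e, float(rng.uniform(0.72, 0.82)))
                )
            # sub-threshold decoy blocks
            decoy_blocks = _place_blocks(
                rng, L, [200, 200], [(r.start, r.end) for r in regions]
            )
            for s, e in decoy_blocks:
                regions.append(ConservedRegion(s, e, float(rng.uniform(0.40, 0.60))))

        def free(start: int, length: int) -> bool:
            return all(start + length <= s or e <= start for s, e in occupied)

        def plant(motif: str, tf: str, start: int) -> None:
            strand = "+" if rng.random() < 0.5 else "-"
            inst = motif if strand == "+" else _revcomp(motif)
            promoter[start : start + len(inst)] = np.frombuffer(
                inst.encode(), dtype="S1"
            )
            occupied.append((start, start + len(inst)))
            planted.append(PlantedSite(gene_id, tf, start, strand))

        anchors_here: list[tuple[int, int]] = []
        if gene_id in anchor_genes and fp is not None:
            fp_start, fp_end = fp
            amot = config.anchor_motif
            # variable anchor count and spacing: promoters differ in both the
            # number of anchor sites and the searchable flank geometry
            n_here = int(rng.integers(1, config.n_anchor_sites + 1))
            start = fp_start + int(rng.integers(10, 41))
            for _ in range(n_here):
                if start + len(amot) > fp_end:
                    break
                plant(amot, ANCHOR_TF, start)
                anchors_here.append((start, start + len(amot)))
                start = start + len(amot) + int(rng.integers(80, 261))
            if (gene_id in cofactor_genes or gene_id in bg_cof) and anchors_here:
                a_start, a_end = anchors_here[0]
                for _ in range(20):
                    gap = int(rng.integers(10, 80))
                    pos = a_end + gap
                    if pos + len(config.cofactor_motif) <= fp_end and free(
                        pos, len(config.cofactor_motif)
                    ):
                        plant(config.cofactor_motif, COFACTOR_TF, pos)
                        break

        # decoy TF sites inside conserved (>= 0.7 identity) blocks, with a
        # Poisson-distributed per-promoter site count
        good_blocks = [r for r in regions if r.identity >= 0.70]
        for tf in decoys:
            if not good_blocks:
                continue
            motif = decoy_consensus[tf]
            for _ in range(int(rng.poisson(config.decoy_site_rate))):
                for _ in range(20):
                    block = good_blocks[rng.integers(len(good_blocks))]
                    if block.length <= len(motif):
                        continue
                    start = int(
                        rng.integers(block.start, block.end - len(motif))
                    )
                    if free(start, len(motif)):
                        plant(motif, tf, start)
                        break

        idx = i
        gene = GeneModel(
            gene_id=gene_id,
            transcript=transcripts[idx],
            promoter=promoter.tobytes().decode(),
            tss=tss,
            baseline_mean=float(means[idx]),
        )
        genes.append(gene)
        conservation[gene_id] = sorted(regions, key=lambda r: r.start)

    for j, idx in enumerate(de_idx):
        genes[idx].is_de = True
        genes[idx].de_direction = str(de_dirs[j])
        genes[idx].de_fold = config.de_fold

    # annotation table: random terms plus the one enriched term
    term_pairs: list[tuple[str, str]] = []
    for t in range(config.n_terms):
        size = int(rng.integers(10, 51))
        members = rng.choice(gene_ids, size=min(size, n), replace=False)
        term_pairs.extend((f"GO:{t:07d}", str(g)) for g in members)
    term_pairs.extend((ENRICHED_TERM, g) for g in sorted(enriched_members))
    annotations = AnnotationTable.from_pairs(term_pairs, universe=gene_ids)

    truth = GroundTruth(
        de_genes={
            gene_ids[idx]: (str(de_dirs[j]), config.de_fold)
            for j, idx in enumerate(de_idx)
        },
        planted_sites=planted,
        enriched_term=ENRICHED_TERM,
        enriched_term_genes=enriched_members,
        anchor_genes=anchor_genes,
        target_genes=target_genes,
        cofactor_genes=cofactor_genes,
    )
    transcriptome = Transcriptome(
        config=config,
        genes=genes,
        conservation=conservation,
        annotations=annotations,
        tf_sites=tf_sites,
        ground_truth=truth,
    )
    return transcriptome, truth


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(means)
    r = 1.0 / config.dispersion
    p = r / (r + np.maximum(means, 1e-12))
    return rng.negative_binomial(r, p)


def simulate_libraries(
    transcriptome: Transcriptome,
    config: SimulationConfig | None = None,
) -> list[SimulatedLibrary]:
    """Sample 2 genotypes x n_stages tag libraries from the gene models.

    Gene counts follow the configured noise model around the genotype means;
    spiked genes carry the configured mutant/wild-type fold.  Singleton
    noise tags are added so that the configured fraction of useful tags are
    singletons, plus small contaminant classes (N-base, linker and
    low-quality tags) that the filtering step removes.  Raw records are
    returned alongside the filtered library.
    """
    config = config or transcriptome.config
    rng = _rng(config, 1)
    libraries: list[SimulatedLibrary] = []
    gene_tags = [(g, g.tag) for g in transcriptome.genes]
    for stage in config.stage_labels:
        for genotype in ("Wt", "mutant"):
            records: list[TagRecord] = []
            means = np.array(
                [
                    g.baseline_mean if genotype == "Wt" else g.mutant_mean()
                    for g, _ in gene_tags
                ]
            )
            counts = _draw_counts(rng, means, config)
            for (gene, tag), count in zip(gene_tags, counts):
                if count > 0 and tag is not None:
                    quality = 0.99 + 0.01 * float(rng.random())
                    records.append(TagRecord(tag, int(count), quality))
            useful_total = sum(r.count for r in records)
            # singleton noise tags: fraction f of useful tags observed once
            f = config.singleton_fraction
            n_single = int(round(f * useful_total / (1.0 - f))) if f < 1 else 0
            seen = {r.tag for r in records}
            for _ in range(n_single):
                while True:
                    tag = "CATG" + _random_seq(rng, 17).tobytes().decode()
                    if tag not in seen:
                        seen.add(tag)
                        break
                records.append(TagRecord(tag, 1, 0.99 + 0.01 * float(rng.random())))
            # contaminants removed by filtering
            n_cont = int(round(config.contaminant_fraction * len(records)))
            for _ in range(n_cont):
                kind = rng.integers(0, 3)
                if kind == 0:  # one N base call
                    seq = _random_seq(rng, 17).tobytes().decode()
                    pos = int(rng.integers(0, 17))
                    tag = "CATG" + seq[:pos] + "N" + seq[pos + 1 :]
                    records.append(TagRecord(tag, 1, 0.995))
                elif kind == 1:  # linker artefact
                    tag = sorted(LINKER_TAGS)[int(rng.integers(len(LINKER_TAGS)))]
                    records.append(TagRecord(tag, int(rng.integers(1, 5)), 0.995))
                else:  # low sequence quality
                    tag = "CATG" + _random_seq(rng, 17).tobytes().decode()
                    records.append(
                        TagRecord(tag, 1, float(rng.uniform(0.90, 0.9899)))
                    )
            result = sage_diff.filter_tags(records, linker_tags=LINKER_TAGS)
            library = SageLibrary.from_records(
                result.kept,
                id=f"{genotype}_{stage}",
                genotype=genotype,
                stage=stage,
                total_raw=sum(r.count for r in records),
            )
            libraries.append(
                SimulatedLibrary(
                    raw_records=records, library=library, filter_result=result
                )
            )
    return libraries
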