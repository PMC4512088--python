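"""Anchored co-factor over-representation analysis.

Given an anchor transcription factor (here NR2E1) with predicted sites on a
set of target promoters and on a background promoter set, this module asks
which other TFs have predicted sites clustered within a fixed window
(default 100 bp) of the anchor sites more often in targets than expected.

Two statistics are computed per candidate TF:

* a gene-hit Fisher score -- the one-tailed hypergeometric probability of
  seeing at least the observed number of target genes carrying a proximal
  site, against the background gene-hit rate; and
* a site-rate Z-score -- a continuity-corrected binomial comparison of the
  proximal-site density (sites per searchable nucleotide) in targets versus
  background.

Significance of both is then re-assessed empirically against random
same-size gene sets drawn from a candidate pool, reporting n/N: the
fraction of trials scoring more significant than the observed set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .motif import PredictedSite

__all__ = [
    "AnchoredSiteSet",
    "CofactorResult",
    "EmpiricalNull",
    "EmpiricalP",
    "anchored_sites",
    "fisher_score",
    "z_score",
    "empirical_p",
    "run_cofactor_analysis",
    "CofactorAnalysis",
]

Interval = tuple[int, int]


def _union_length(intervals: Iterable[Interval]) -> int:
    total, last_end = 0, None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


@dataclass
class AnchoredSiteSet:
    """Per-gene anchor sites plus other-TF sites proximal to them.

    ``searchable_nt`` is the number of nucleotides within ``window`` bp of an
    anchor after excluding the anchor bases themselves -- the denominator of
    the site-density rate.
    """

    gene_id: str
    anchors: list[PredictedSite]
    proximal: dict[str, list[PredictedSite]]
    searchable_nt: int

    def site_count(self, tf: str) -> int:
        return len(self.proximal.get(tf, ()))

    def has_hit(self, tf: str) -> bool:
        return bool(self.proximal.get(tf))


def anchored_sites(
    anchors: Sequence[PredictedSite],
    others: Mapping[str, Sequence[PredictedSite]],
    window: int = 100,
    gene_id: str = "",
) -> AnchoredSiteSet:
    """Select other-TF sites within ``window`` bp of an anchor site.

    A site is kept when the gap between its interval and the nearest anchor
    interval is at most ``window`` and it shares no base with any anchor
    (sites overlapping an anchor motif are excluded).  With no anchors the
    proximal set is empty and the searchable length zero.
    """
    anchor_iv = [(a.start, a.end) for a in anchors]
    proximal: dict[str, list[PredictedSite]] = {}
    for tf, sites in others.items():
        kept = []
        for site in sites:
            overlaps = any(site.start < e and s < site.end for s, e in anchor_iv)
            if overlaps:
                continue
            near = any(
                max(s - site.end, site.start - e, 0) <= window
                for s, e in anchor_iv
            )
            if near:
                kept.append(site)
        proximal[tf] = kept
    flanks = [(max(0, s - window), e + window) for s, e in anchor_iv]
    searchable = _union_length(flanks) - _union_length(anchor_iv)
    return AnchoredSiteSet(
        gene_id=gene_id,
        anchors=list(anchors),
        proximal=proximal,
        searchable_nt=searchable,
    )


def fisher_score(
    target_hits: int, target_size: int, bg_hits: int, bg_size: int
) -> float:
    """One-tailed Fisher exact probability of the target gene-hit count.

    P(X >= target_hits) under the hypergeometric with population
    target_size + bg_size, target_hits + bg_hits successes and target_size
    draws; exact combinatorics evaluated in log space.
    """
    if not (0 <= target_hits <= target_size and 0 <= bg_hits <= bg_size):
        raise ValueError("hit counts must not exceed set sizes")
    return float(
        hypergeom.sf(
            target_hits - 1,
            target_size + bg_size,
            target_hits + bg_hits,
            target_size,
        )
    )


def z_score(
    target_sites: int, target_nt: int, bg_sites: int, bg_nt: int
) -> float:
    """Continuity-corrected binomial rate Z-score of target site density.

    With background rate p = bg_sites / bg_nt and expectation
    u = p * target_nt,

        z = (target_sites - u - 0.5) / sqrt(target_nt * p * (1 - p)),

    positive when the target site rate exceeds background.  A background
    with zero sites is floored at half a site to keep the null variance
    defined.
    """
    if bg_nt <= 0 or target_nt <= 0:
        raise ValueError("searchable nucleotide counts must be positive")
    if bg_sites > bg_nt:
        raise ValueError("bg_sites cannot exceed bg_nt")
    p = (bg_sites if bg_sites > 0 else 0.5) / bg_nt
    p = min(p, 1.0 - 1e-12)
    u = p * target_nt
    sd = math.sqrt(target_nt * p * (1.0 - p))
    return (target_sites - u - 0.5) / sd


@dataclass(frozen=True)
class EmpiricalP:
    """Empirical p-value n/N; n = 0 is reported as the bound '< 1/N'."""

    n_more: int
    n_trials: int

    @property
    def value(self) -> float:
        return self.n_more / self.n_trials

    @property
    def is_bound(self) -> bool:
        return self.n_more == 0

    def __str__(self) -> str:
        if self.is_bound:
            return f"< {1.0 / self.n_trials:g}"
        return f"= {self.value:g}"


@dataclass
class EmpiricalNull:
    """Null score distributions from random same-size gene-set trials."""

    n_trials: int
    seed: int | None
    z: dict[str, np.ndarray] = field(default_factory=dict)
    fisher: dict[str, np.ndarray] = field(default_factory=dict)


def empirical_p(
    observed: float, null_scores: Sequence[float], better: str
) -> EmpiricalP:
    """Fraction of null trials strictly more significant than ``observed``.

    ``better="greater"`` counts trials with score > observed (Z-scores);
    ``better="less"`` counts trials with score < observed (Fisher scores).
    Ties count as not more significant.
    """
    arr = np.asarray(null_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empirical null must contain at least one trial")
    if better == "greater":
        n = int((arr > observed).sum())
    elif better == "less":
        n = int((arr < observed).sum())
    else:
        raise ValueError("better must be 'greater' or 'less'")
    return EmpiricalP(n_more=n, n_trials=arr.size)


@dataclass(frozen=True)
class CofactorResult:
    """Per-TF co-factor over-representation summary (one Table-style row)."""

    tf_id: str
    target_hits: int
    target_nonhits: int
    bg_hits: int
    bg_nonhits: int
    target_sites: int
    bg_sites: int
    target_nt: int
    bg_nt: int
    z: float
    fisher: float
    empirical_p_z: EmpiricalP | None = None
    empirical_p_fisher: EmpiricalP | None = None

    def to_row(self) -> dict:
        return {
            "tf": self.tf_id,
            "bg_hits": self.bg_hits,
            "bg_nonhits": self.bg_nonhits,
            "target_hits": self.target_hits,
            "target_nonhits": self.target_nonhits,
            "target_sites": self.target_sites,
            "bg_sites": self.bg_sites,
            "target_nt": self.target_nt,
            "bg_nt": self.bg_nt,
            "z_score": self.z,
            "fisher_score": self.fisher,
            "empirical_p_z": str(self.empirical_p_z) if self.empirical_p_z else "",
            "empirical_p_fisher": (
                str(self.empirical_p_fisher) if self.empirical_p_fisher else ""
            ),
        }


@dataclass
class CofactorAnalysis:
    """Full analysis output: enriched TFs, all per-TF results, and the null."""

    enriched: list[CofactorResult]
    results: list[CofactorResult]
    null: EmpiricalNull | None
    target_genes: list[str]
    z_min: float
    fisher_max: float


def _z_vec(sites: np.ndarray, nt: np.ndarray, bg_sites: np.ndarray, bg_nt: int):
    """Vectorised counterpart of :func:`z_score` (same formula)."""
    p = np.minimum(np.where(bg_sites > 0, bg_sites, 0.5) / bg_nt, 1.0 - 1e-12)
    nt = np.asarray(nt, dtype=float)
    u = p * nt[..., None] if np.ndim(nt) else p * nt
    sd = np.sqrt((nt[..., None] if np.ndim(nt) else nt) * p * (1.0 - p))
    return (sites - u - 0.5) / sd


def run_cofactor_analysis(
    target_genes: Sequence[str],
    pool_genes: Sequence[str],
    background_genes: Sequence[str],
    gene_sites: Mapping[str, Mapping[str, Sequence[PredictedSite]]],
    anchor_tf: str,
    window: int = 100,
    z_min: float = 10.0,
    fisher_max: float = 0.01,
    trials: int = 1000,
    seed: int | None = None,
) -> CofactorAnalysis:
    """Anchored co-factor over-representation with an empirical null.

    ``gene_sites`` maps gene -> tf -> footprint-filtered predicted sites
    (the anchor TF included).  Targets and background must be disjoint uses
    of that mapping; the empirical null draws ``trials`` random sets of
    len(target_genes) genes without replacement from ``pool_genes`` and
    recomputes both scores against the same fixed background.  Deterministic
    given ``seed``.
    """
    targets = list(target_genes)
    pool = list(pool_genes)
    if len(pool) < len(targets):
        raise ValueError("candidate pool smaller than the target set")
    tfs = sorted(
        {tf for sites in gene_sites.values() for tf in sites if tf != anchor_tf}
    )
    all_genes = sorted(set(targets) | set(pool) | set(background_genes))
    anchored: dict[str, AnchoredSiteSet] = {}
    for gene in all_genes:
        sites = gene_sites.get(gene, {})
        anchors = sites.get(anchor_tf, [])
        others = {tf: sites.get(tf, []) for tf in tfs}
        anchored[gene] = anchored_sites(anchors, others, window=window, gene_id=gene)

    # per-gene summary arrays: gene x tf hit/site matrices and searchable nt
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    S = np.array(
        [[anchored[g].site_count(tf) for tf in tfs] for g in all_genes], dtype=int
    ).reshape(len(all_genes), len(tfs))
    H = (S > 0).astype(int)
    NT = np.array([anchored[g].searchable_nt for g in all_genes], dtype=int)

    def aggregate(genes: Sequence[str]):
        idx = [gene_pos[g] for g in genes]
        return H[idx].sum(axis=0), S[idx].sum(axis=0), int(NT[idx].sum())

    bg_hits, bg_sites, bg_nt = aggregate(background_genes)
    t_hits, t_sites, t_nt = aggregate(targets)
    n_t, n_bg = len(targets), len(background_genes)
    if bg_nt <= 0:
        raise ValueError("background set has no searchable sequence near anchors")

    def fisher_vec(hits):
        return hypergeom.sf(hits - 1, n_t + n_bg, hits + bg_hits, n_t)

    obs_z = _z_vec(t_sites, np.asarray(t_nt), bg_sites, bg_nt)
    obs_fisher = fisher_vec(t_hits)

    null = None
    emp_z: list[EmpiricalP | None] = [None] * len(tfs)
    emp_f: list[EmpiricalP | None] = [None] * len(tfs)
    if trials > 0:
        rng = np.random.default_rng(seed)
        null = EmpiricalNull(n_trials=trials, seed=seed)
        pool_idx = np.array([gene_pos[g] for g in pool])
        draws = np.stack(
            [rng.choice(pool_idx, size=n_t, replace=False) for _ in range(trials)]
        )
        trial_hits = H[draws].sum(axis=1)
        trial_sites = S[draws].sum(axis=1)
        trial_nt = NT[draws].sum(axis=1)
        null_z = _z_vec(trial_sites, trial_nt, bg_sites, bg_nt)
        null_f = fisher_vec(trial_hits)
        for i, tf in enumerate(tfs):
            null.z[tf] = null_z[:, i]
            null.fisher[tf] = null_f[:, i]
            emp_z[i] = empirical_p(obs_z[i], null_z[:, i], better="greater")
            emp_f[i] = empirical_p(obs_fisher[i], null_f[:, i], better="less")
    else:
        warnings.warn(
            "trials=0: co-factor scores reported without empirical p-values",
            stacklevel=2,
        )

    results = []
    for i, tf in enumerate(tfs):
        results.append(
            CofactorResult(
                tf_id=tf,
                target_hits=int(t_hits[i]),
                target_nonhits=n_t - int(t_hits[i]),
                bg_hits=int(bg_hits[i]),
                bg_nonhits=n_bg - int(bg_hits[i]),
                target_sites=int(t_sites[i]),
                bg_sites=int(bg_sites[i]),
                target_nt=t_nt,
                bg_nt=bg_nt,
                z=float(obs_z[i]),
                fisher=float(obs_fisher[i]),
                empirical_p_z=emp_z[i],
                empirical_p_fisher=emp_f[i],
            )
        )
    results.sort(key=lambda r: -r.z)
    enriched = [r for r in results if r.z > z_min and r.fisher < fisher_max]
    return CofactorAnalysis(
        enriched=enriched,
        results=results,
        null=null,
        target_genes=targets,
        z_min=z_min,
        fisher_max=fisher_max,
    )
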