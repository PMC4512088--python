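"""Binding-site profile construction, promoter scanning and footprint filtering.

A position frequency matrix (PFM) tallies base counts per column over a set
of equal-length binding-site sequences; the log-odds position weight matrix
(PWM) scores candidate windows against a background composition, and sites
are reported at a relative score threshold

    rel = (score - min_score) / (max_score - min_score)

with 0.80 as the working default.  Predictions are then restricted to
phylogenetically footprinted sub-regions: conserved blocks at >= 70 %
identity, ranked by identity until a top fraction (default 10 %) of the
sequence length is covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "Pfm",
    "Pwm",
    "PredictedSite",
    "ConservedRegion",
    "build_pfm",
    "pwm_from_pfm",
    "scan",
    "footprint_filter",
    "retained_regions",
    "merge_regions",
    "conservation_from_alignment",
    "promoter_region",
    "discover_motif",
    "MotifDiscovery",
]


@dataclass(frozen=True)
class Pfm:
    """Position frequency matrix: 4 x L base counts (rows A, C, G, T)."""

    counts: np.ndarray
    n_sites: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape[0] != 4 or counts.ndim != 2:
            raise ValueError("PFM must be 4 x L")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        sums = counts.sum(axis=0)
        if not np.allclose(sums, self.n_sites):
            raise ValueError("every PFM column must sum to n_sites")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class Pwm:
    """Log-odds weight matrix with background and score range."""

    weights: np.ndarray
    background: np.ndarray
    tf_id: str = "TF"

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def relative(self, score: float) -> float:
        return (score - self.min_score) / (self.max_score - self.min_score)

    def score(self, window: str) -> float:
        """Absolute log-odds score of one window (must match the PWM length)."""
        if len(window) != self.length:
            raise ValueError("window length mismatch")
        return float(
            sum(self.weights[_BASE_INDEX[b], i] for i, b in enumerate(window))
        )


@dataclass(frozen=True)
class PredictedSite:
    """A scored motif occurrence, forward-strand coordinates, 0-based half-open."""

    tf_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    score: float
    rel_score: float


@dataclass(frozen=True)
class ConservedRegion:
    """Promoter-relative conserved interval with percent identity in [0, 1]."""

    start: int
    end: int
    identity: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty conserved region")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


def build_pfm(sites: Sequence[str]) -> Pfm:
    """Tally a PFM from >= 2 equal-length ACGT binding-site sequences."""
    if len(sites) < 2:
        raise ValueError("need at least two site sequences")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("site sequences must have equal length")
    counts = np.zeros((4, length))
    for site in sites:
        for i, base in enumerate(site.upper()):
            if base not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {base!r} in site {site!r}")
            counts[_BASE_INDEX[base], i] += 1
    return Pfm(counts=counts, n_sites=len(sites))


def pwm_from_pfm(
    pfm: Pfm,
    pseudocount: float = 0.8,
    background: Sequence[float] | None = None,
    tf_id: str = "TF",
) -> Pwm:
    """Log-odds PWM with a background-distributed pseudocount.

    weight(b, i) = log2( (count(b,i) + pc * bg_b) / ((n_sites + pc) * bg_b) )
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    if not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must sum to 1")
    num = pfm.counts + pseudocount * bg[:, None]
    den = (pfm.n_sites + pseudocount) * bg[:, None]
    return Pwm(weights=np.log2(num / den), background=bg, tf_id=tf_id)


def _encode(sequence: str) -> np.ndarray:
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    codes = np.full(seq.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[seq == ord(base)] = idx
    return codes


def _window_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every window; windows containing non-ACGT bases score NaN."""
    length = weights.shape[1]
    n_win = codes.size - length + 1
    if n_win <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, length)
    valid = (wins >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        v = wins[valid]
        scores[valid] = weights[v, np.arange(length)].sum(axis=1)
    return scores


def scan(
    pwm: Pwm,
    sequence: str,
    rel_threshold: float = 0.80,
    both_strands: bool = True,
    gene_id: str = "",
) -> list[PredictedSite]:
    """Report every window with relative score >= threshold on either strand.

    Minus-strand sites are scored on the reverse complement; coordinates are
    always reported on the forward strand.  Windows containing N are skipped.
    """
    codes = _encode(sequence)
    length = pwm.length
    if codes.size < length:
        return []
    span = pwm.max_score - pwm.min_score
    sites: list[PredictedSite] = []
    strands = [("+", pwm.weights)]
    if both_strands:
        # reverse complement of the matrix: complement rows, reverse columns
        strands.append(("-", pwm.weights[::-1, ::-1]))
    for strand, weights in strands:
        scores = _window_scores(weights, codes)
        with np.errstate(invalid="ignore"):
            rel = (scores - pwm.min_score) / span
            hits = np.nonzero(rel >= rel_threshold)[0]
        for start in hits:
            sites.append(
                PredictedSite(
                    tf_id=pwm.tf_id,
                    gene_id=gene_id,
                    start=int(start),
                    end=int(start) + length,
                    strand=strand,
                    score=float(scores[start]),
                    rel_score=float(rel[start]),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def merge_regions(regions: Iterable[ConservedRegion]) -> list[ConservedRegion]:
    """Merge overlapping/adjacent regions; merged identity is the length-weighted mean."""
    ordered = sorted(regions, key=lambda r: (r.start, r.end))
    merged: list[ConservedRegion] = []
    for region in ordered:
        if merged and region.start <= merged[-1].end:
            prev = merged.pop()
            end = max(prev.end, region.end)
            ident = (
                prev.identity * prev.length + region.identity * region.length
            ) / (prev.length + region.length)
            merged.append(ConservedRegion(prev.start, end, ident))
        else:
            merged.append(region)
    return merged


def retained_regions(
    regions: Sequence[ConservedRegion],
    min_identity: float = 0.70,
    top_fraction: float = 0.10,
    total_length: int | None = None,
) -> list[ConservedRegion]:
    """Conserved regions surviving the footprint thresholds.

    Regions below ``min_identity`` are discarded; the remainder are ranked by
    identity (ties by start) and retained until their cumulative length
    reaches ``top_fraction`` of ``total_length`` (default: the summed length
    of all supplied regions).  The region crossing the budget is included.
    """
    if total_length is None:
        total_length = sum(r.length for r in regions)
    budget = top_fraction * total_length
    eligible = sorted(
        (r for r in regions if r.identity >= min_identity),
        key=lambda r: (-r.identity, r.start),
    )
    kept: list[ConservedRegion] = []
    covered = 0
    for region in eligible:
        if covered >= budget:
            break
        kept.append(region)
        covered += region.length
    return kept


def footprint_filter(
    sites: Iterable[PredictedSite],
    regions: Sequence[ConservedRegion],
    min_identity: float = 0.70,
    top_fraction: float = 0.10,
    total_length: int | None = None,
) -> list[PredictedSite]:
    """Keep only sites lying fully inside a retained conserved region."""
    kept_regions = retained_regions(regions, min_identity, top_fraction, total_length)
    out = [
        s
        for s in sites
        if any(r.start <= s.start and s.end <= r.end for r in kept_regions)
    ]
    return out


def conservation_from_alignment(
    aligned_a: str,
    aligned_b: str,
    window: int = 100,
    threshold: float = 0.70,
) -> list[ConservedRegion]:
    """Sliding-window percent identity of a pairwise alignment.

    Identity per window is matches / window with gaps counted as mismatches;
    maximal runs of windows at or above ``threshold`` are merged into regions
    whose coordinates are mapped to the ungapped first sequence.  The
    reported identity of a region is its column-wise match fraction.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    n = len(aligned_a)
    a = np.frombuffer(aligned_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(aligned_b.upper().encode(), dtype=np.uint8)
    match = ((a == b) & (a != ord("-"))).astype(float)
    if n < window:
        window = n
    csum = np.concatenate([[0.0], np.cumsum(match)])
    win_ident = (csum[window:] - csum[:-window]) / window
    above = win_ident >= threshold
    # ungapped coordinate of each alignment column in sequence a
    not_gap = (a != ord("-")).astype(int)
    ungapped = np.concatenate([[0], np.cumsum(not_gap)])
    regions: list[ConservedRegion] = []
    i = 0
    n_win = above.size
    while i < n_win:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n_win and above[j]:
            j += 1
        aln_start, aln_end = i, j - 1 + window
        start, end = int(ungapped[aln_start]), int(ungapped[aln_end])
        if end > start:
            ident = float(match[aln_start:aln_end].mean())
            regions.append(ConservedRegion(start, end, min(ident, 1.0)))
        i = j
    return merge_regions(regions)


def promoter_region(tss: int, flank: int = 5000) -> tuple[int, int]:
    """Scanning interval around a TSS: [max(0, tss - flank), tss + flank + 1)."""
    if tss < 0:
        raise ValueError("tss must be non-negative")
    return (max(0, tss - flank), tss + flank + 1)


@dataclass
class MotifDiscovery:
    """Result of one-occurrence-per-sequence motif discovery."""

    offsets: list[int]
    pfm: Pfm
    log_likelihood: float

    @property
    def consensus(self) -> str:
        return self.pfm.consensus


def discover_motif(
    sequences: Sequence[str],
    width: int,
    n_restarts: int = 8,
    n_iter: int = 60,
    seed: int | None = 0,
) -> MotifDiscovery:
    """Ungapped motif discovery, one occurrence per sequence.

    A simplified EM in the spirit of classic one-occurrence-per-sequence
    motif finders: soft responsibilities over all width-``width`` windows of
    each sequence, a profile M-step with a small pseudocount, multiple seeded
    random restarts, and the restart with the best log likelihood kept.  The
    final offsets are the per-sequence maximum-responsibility windows.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    if any(len(s) < width for s in sequences):
        raise ValueError("every sequence must be at least as long as width")
    rng = np.random.default_rng(seed)
    coded = [_encode(s) for s in sequences]
    if any((c < 0).any() for c in coded):
        raise ValueError("sequences must be over ACGT")
    windows = [
        np.lib.stride_tricks.sliding_window_view(c, width) for c in coded
    ]
    # background from overall composition
    all_codes = np.concatenate(coded)
    bg = np.bincount(all_codes, minlength=4).astype(float)
    bg = np.maximum(bg / bg.sum(), 1e-6)
    log_bg = np.log(bg)
    pos = np.arange(width)

    best: tuple[float, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        # init from one random window per sequence, heavily smoothed
        profile = np.full((4, width), 1.0)
        for wins in windows:
            w = wins[rng.integers(len(wins))]
            profile[w, pos] += 2.0
        profile /= profile.sum(axis=0, keepdims=True)
        loglik = -np.inf
        for _ in range(n_iter):
            log_profile = np.log(profile)
            loglik = 0.0
            expected = np.full((4, width), 0.25)  # pseudocount
            for wins in windows:
                llr = (log_profile[wins, pos] - log_bg[wins]).sum(axis=1)
                m = llr.max()
                resp = np.exp(llr - m)
                total = resp.sum()
                resp /= total
                loglik += m + np.log(total / len(wins))
                for base in range(4):
                    expected[base] += ((wins == base) * resp[:, None]).sum(axis=0)
            new_profile = expected / expected.sum(axis=0, keepdims=True)
            if np.abs(new_profile - profile).max() < 1e-9:
                profile = new_profile
                break
            profile = new_profile
        if best is None or loglik > best[0]:
            best = (loglik, profile)

    loglik, profile = best
    log_profile = np.log(profile)
    offsets = []
    for wins in windows:
        llr = (log_profile[wins, pos] - log_bg[wins]).sum(axis=1)
        offsets.append(int(llr.argmax()))

    def hard_counts(offs):
        counts = np.zeros((4, width))
        for wins, off in zip(windows, offs):
            counts[wins[off], pos] += 1
        return counts

    def alignment_llr(counts):
        # log-likelihood ratio of the hard alignment vs background
        n = len(sequences)
        freq = (counts + 0.25) / (n + 1.0)
        return float((counts * (np.log(freq) - log_bg[:, None])).sum())

    # phase polishing: EM frequently converges to a one-column shift of the
    # optimum; try small global shifts of the alignment and keep the best
    best_offsets, best_llr = offsets, alignment_llr(hard_counts(offsets))
    for delta in (-2, -1, 1, 2):
        shifted = [o + delta for o in offsets]
        if any(o < 0 or o >= len(w) for o, w in zip(shifted, windows)):
            continue
        llr = alignment_llr(hard_counts(shifted))
        if llr > best_llr:
            best_offsets, best_llr = shifted, llr
    offsets = best_offsets
    pfm = Pfm(counts=hard_counts(offsets), n_sites=len(sequences))
    return MotifDiscovery(offsets=offsets, pfm=pfm, log_likelihood=float(loglik))
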