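"""Differential tag abundance between LongSAGE libraries.

A LongSAGE library is a multiset of 21-bp tags ("CATG" + 17 bp) counted from
sequenced ditags.  After filtering (N-containing tags, linker artefacts, low
sequence quality), two libraries are compared tag by tag with the
Audic-Claverie exact test, which conditions on the count observed in one
library and asks how surprising the count in the other library is given the
ratio of library sizes.  Fold changes are computed on depth-normalised
counts (tags per 100,000 useful tags) with zero counts raised to one for the
ratio only, never for the significance test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import nbinom

TAG_LENGTH = 21
TAG_ANCHOR = "CATG"

__all__ = [
    "TagRecord",
    "SageLibrary",
    "DifferentialTag",
    "FilterResult",
    "VennPartition",
    "filter_tags",
    "normalize_count",
    "audic_claverie_p",
    "conditional_lower_tail",
    "fold_change",
    "differential_tags",
    "extract_canonical_tag",
    "build_tag_index",
    "map_tags_to_genes",
    "venn_stats",
]


@dataclass(frozen=True)
class TagRecord:
    """A single observed tag: 21-mer sequence, count, mean base quality in [0, 1]."""

    tag: str
    count: int
    quality: float = 1.0


@dataclass
class SageLibrary:
    """One filtered library: tag -> count plus totals and metadata.

    ``total_useful`` is the library size N entering the Audic-Claverie test;
    ``total_raw`` is the pre-filtering tag total and is always >= useful.
    """

    id: str
    genotype: str  # "Wt" or "mutant"
    stage: str
    tags: dict[str, int] = field(default_factory=dict)
    total_raw: int = 0

    @property
    def total_useful(self) -> int:
        return sum(self.tags.values())

    @classmethod
    def from_records(
        cls,
        records: Iterable[TagRecord],
        id: str = "",
        genotype: str = "Wt",
        stage: str = "",
        total_raw: int | None = None,
    ) -> "SageLibrary":
        tags: dict[str, int] = {}
        for rec in records:
            tags[rec.tag] = tags.get(rec.tag, 0) + rec.count
        lib = cls(id=id, genotype=genotype, stage=stage, tags=tags)
        lib.total_raw = lib.total_useful if total_raw is None else total_raw
        return lib


@dataclass(frozen=True)
class DifferentialTag:
    """A tag's paired counts with exact-test p-value and signed fold change.

    ``count_a``/``n_a`` belong to the wild-type library, ``count_b``/``n_b``
    to the mutant; ``fold_change`` is positive when the mutant is higher
    ("up") and negative when lower ("down").
    """

    tag: str
    count_a: int
    count_b: int
    n_a: int
    n_b: int
    p_value: float
    fold_change: float

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 0 else "down"


@dataclass
class FilterResult:
    """Outcome of tag filtering; rejected records are reported, not dropped silently."""

    kept: list[TagRecord]
    removed_n_base: list[TagRecord]
    removed_linker: list[TagRecord]
    removed_quality: list[TagRecord]
    malformed: list[TagRecord]

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_n_base)
            + len(self.removed_linker)
            + len(self.removed_quality)
            + len(self.malformed)
        )


def filter_tags(
    raw: Iterable[TagRecord],
    linker_tags: Iterable[str] = (),
    quality_min: float = 0.99,
) -> FilterResult:
    """Filter a raw tag table.

    Removes tags containing one or more N base calls, linker-derived
    artefact tags, and tags whose mean sequence quality is below
    ``quality_min`` (default 99 %).  Singletons and counts derived from
    duplicated ditags are retained: no abundance-based filtering is applied.
    Records whose tag is not exactly 21 bp are reported under ``malformed``.
    """
    linkers = frozenset(linker_tags)
    out = FilterResult([], [], [], [], [])
    for rec in raw:
        if len(rec.tag) != TAG_LENGTH:
            out.malformed.append(rec)
        elif "N" in rec.tag:
            out.removed_n_base.append(rec)
        elif rec.tag in linkers:
            out.removed_linker.append(rec)
        elif rec.quality < quality_min:
            out.removed_quality.append(rec)
        else:
            out.kept.append(rec)
    return out


def normalize_count(count: int, total_useful: int) -> float:
    """Tags per 100,000 useful tags: (count / total_useful) * 100000."""
    if total_useful <= 0:
        raise ValueError("total_useful must be positive")
    return count / total_useful * 100_000.0


def conditional_lower_tail(x: int, y: int, n1: float, n2: float) -> float:
    """P(Y <= y | x) under the Audic-Claverie conditional distribution.

    Given ``x`` tags in a library of ``n1`` useful tags, the count Y in a
    second library of ``n2`` useful tags follows

        p(y | x) = (n2/n1)^y (x+y)! / (x! y! (1 + n2/n1)^(x+y+1)),

    which is a negative binomial with x+1 successes and success probability
    n1/(n1+n2); the tail is evaluated through that identity in log space.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return float(nbinom.cdf(y, x + 1, n1 / (n1 + n2)))


def audic_claverie_p(
    x: int, y: int, n1: float, n2: float, tail: str = "two_sided"
) -> float:
    """Audic-Claverie exact p-value for counts ``x`` and ``y``.

    The statistic is symmetrised as the smaller of the two conditional lower
    tails, min(P(Y <= y | x), P(X <= x | y)), so that swapping
    (x, n1) <-> (y, n2) leaves the p-value unchanged.  ``tail="one_sided"``
    returns that minimum; ``tail="two_sided"`` (the default used for the
    P < 0.05 screen) doubles it, capped at 1.
    """
    lower = conditional_lower_tail(x, y, n1, n2)
    swapped = conditional_lower_tail(y, x, n2, n1)
    p = min(lower, swapped)
    if tail == "one_sided":
        return max(p, math.ulp(0.0))
    if tail == "two_sided":
        return min(1.0, 2.0 * p) if p < 0.5 else 1.0
    raise ValueError(f"unknown tail {tail!r}")


def fold_change(
    x: int, y: int, n1: float, n2: float, zero_adjust: int = 1
) -> float:
    """Signed fold change of mutant (y) over wild type (x) on normalised counts.

    Zero counts are adjusted to ``zero_adjust`` (default 1) before
    normalisation -- for the fold change only.  The magnitude is
    max(a, b)/min(a, b) of the two tags-per-100k values; the sign is positive
    when the mutant value exceeds wild type and negative when it is lower, so
    a gene silenced in the mutant reports e.g. -7.3.  Equal values give +1.0.
    """
    a = normalize_count(max(x, zero_adjust), n1)
    b = normalize_count(max(y, zero_adjust), n2)
    magnitude = max(a, b) / min(a, b)
    return magnitude if b >= a else -magnitude


def differential_tags(
    lib_a: SageLibrary,
    lib_b: SageLibrary,
    alpha: float = 0.05,
    tail: str = "two_sided",
) -> list[DifferentialTag]:
    """Tags differentially abundant between a wild-type and a mutant library.

    Both libraries must already be filtered (an N-containing tag raises).
    Every tag present in at least one library is tested; exactly the tags
    with p < ``alpha`` are returned, with signed fold change (mutant vs
    wild type) and direction.
    """
    for lib in (lib_a, lib_b):
        if any("N" in t for t in lib.tags):
            raise ValueError(
                f"library {lib.id!r} contains N-base tags; run filter_tags first"
            )
    n1, n2 = lib_a.total_useful, lib_b.total_useful
    results: list[DifferentialTag] = []
    for tag in sorted(set(lib_a.tags) | set(lib_b.tags)):
        x = lib_a.tags.get(tag, 0)
        y = lib_b.tags.get(tag, 0)
        if x + y == 0:
            continue
        p = audic_claverie_p(x, y, n1, n2, tail=tail)
        if p < alpha:
            results.append(
                DifferentialTag(tag, x, y, n1, n2, p, fold_change(x, y, n1, n2))
            )
    return results


def extract_canonical_tag(sequence: str) -> str | None:
    """Canonical LongSAGE tag of a transcript, or None.

    The tag is "CATG" plus the 17 bases immediately 3' of the 3'-most NlaIII
    site (CATG) that still has >= 17 downstream bases.
    """
    limit = len(sequence) - TAG_LENGTH
    # rfind with end=limit+4 only matches CATG starts at <= limit, i.e. with
    # at least 17 bases downstream
    pos = sequence.rfind(TAG_ANCHOR, 0, limit + len(TAG_ANCHOR))
    if pos < 0:
        return None
    return sequence[pos : pos + TAG_LENGTH]


def build_tag_index(transcripts: Mapping[str, str]) -> dict[str, list[str]]:
    """Map canonical tag -> sorted gene ids, from gene -> transcript sequence."""
    index: dict[str, list[str]] = {}
    for gene, seq in transcripts.items():
        tag = extract_canonical_tag(seq)
        if tag is not None:
            index.setdefault(tag, []).append(gene)
    for genes in index.values():
        genes.sort()
    return index


@dataclass
class TagMapping:
    """Tag -> gene assignment with ambiguity and unmapped reporting."""

    mapped: dict[str, list[str]]
    ambiguous: set[str]
    unmapped: set[str]

    def genes(self) -> set[str]:
        return {g for genes in self.mapped.values() for g in genes}


def map_tags_to_genes(
    tags: Iterable[str], index: Mapping[str, Sequence[str]]
) -> TagMapping:
    """Exact-match lookup of tags in a canonical-tag index.

    A tag matching transcripts of several genes is assigned to all of them
    and flagged ambiguous; tags absent from the index are reported unmapped.
    """
    mapped: dict[str, list[str]] = {}
    ambiguous: set[str] = set()
    unmapped: set[str] = set()
    for tag in tags:
        genes = index.get(tag)
        if not genes:
            unmapped.add(tag)
            continue
        mapped[tag] = list(genes)
        if len(genes) > 1:
            ambiguous.add(tag)
    return TagMapping(mapped, ambiguous, unmapped)


@dataclass(frozen=True)
class VennPartition:
    """Seven-region partition of three stage gene sets with derived percentages.

    ``exclusive`` holds the three stage-specific counts, ``pairwise_only``
    the three two-way-only counts ordered (AB, BC, AC), ``triple`` the
    three-way overlap.  Percentages follow the printed arithmetic: stage
    specificity uses the stage total as denominator, pairwise overlap is the
    Jaccard fraction of the two-stage union, and the triple overlap is taken
    over the full union.
    """

    labels: tuple[str, str, str]
    exclusive: tuple[int, int, int]
    pairwise_only: tuple[int, int, int]  # (AB, BC, AC), triple excluded
    triple: int

    @property
    def stage_totals(self) -> tuple[int, int, int]:
        ab, bc, ac = self.pairwise_only
        a, b, c = self.exclusive
        return (
            a + ab + ac + self.triple,
            b + ab + bc + self.triple,
            c + bc + ac + self.triple,
        )

    @property
    def union_total(self) -> int:
        return sum(self.exclusive) + sum(self.pairwise_only) + self.triple

    @property
    def specific_pct(self) -> tuple[float, float, float]:
        return tuple(
            100.0 * e / t if t else 0.0
            for e, t in zip(self.exclusive, self.stage_totals)
        )

    @property
    def pairwise_pct(self) -> dict[tuple[str, str], float]:
        ab, bc, ac = self.pairwise_only
        ta, tb, tc = self.stage_totals
        out = {}
        for (i, j), shared in (((0, 1), ab), ((1, 2), bc), ((0, 2), ac)):
            inter = shared + self.triple
            union = (
                self.stage_totals[i] + self.stage_totals[j] - inter
            )
            out[(self.labels[i], self.labels[j])] = (
                100.0 * inter / union if union else 0.0
            )
        return out

    @property
    def triple_pct(self) -> float:
        return 100.0 * self.triple / self.union_total if self.union_total else 0.0

    @property
    def mean_specific_pct(self) -> float:
        return sum(self.specific_pct) / 3.0

    @property
    def mean_pairwise_pct(self) -> float:
        vals = list(self.pairwise_pct.values())
        return sum(vals) / len(vals)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "exclusive": list(self.exclusive),
            "pairwise_only": list(self.pairwise_only),
            "triple": self.triple,
            "stage_totals": list(self.stage_totals),
            "union_total": self.union_total,
            "specific_pct": list(self.specific_pct),
            "pairwise_pct": {f"{a}|{b}": v for (a, b), v in self.pairwise_pct.items()},
            "triple_pct": self.triple_pct,
            "mean_specific_pct": self.mean_specific_pct,
            "mean_pairwise_pct": self.mean_pairwise_pct,
        }


def venn_stats(
    set_a: set,
    set_b: set,
    set_c: set,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Seven-region Venn partition of three gene sets."""
    triple = set_a & set_b & set_c
    ab = (set_a & set_b) - triple
    bc = (set_b & set_c) - triple
    ac = (set_a & set_c) - triple
    a = set_a - set_b - set_c
    b = set_b - set_a - set_c
    c = set_c - set_a - set_b
    return VennPartition(
        labels=tuple(labels),
        exclusive=(len(a), len(b), len(c)),
        pairwise_only=(len(ab), len(bc), len(ac)),
        triple=len(triple),
    )
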