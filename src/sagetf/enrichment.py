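"""Annotation-term over-representation with the EASE-modified Fisher test.

The EASE score is a conservative variant of the one-tailed Fisher exact
test: the observed overlap k is reduced by one before computing the
hypergeometric upper tail, so single-gene overlaps are never significant.
Terms are Bonferroni-corrected over the number of terms actually tested and
terms backed by fewer than ``min_genes`` submitted genes are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom

__all__ = ["AnnotationTable", "TermResult", "ease_p", "fisher_p", "enrich"]


@dataclass
class AnnotationTable:
    """term -> gene set annotations over a background gene universe."""

    term_to_genes: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        stray = set().union(*self.term_to_genes.values(), set()) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} annotated genes missing from the universe"
            )

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], universe: Iterable[str] | None = None
    ) -> "AnnotationTable":
        mapping: dict[str, set[str]] = {}
        genes: set[str] = set()
        for term, gene in pairs:
            mapping.setdefault(term, set()).add(gene)
            genes.add(gene)
        return cls(mapping, set(universe) if universe is not None else genes)


@dataclass(frozen=True)
class TermResult:
    term: str
    k: int  # submitted genes carrying the term
    n: int  # submitted list size (in-universe)
    K: int  # background genes carrying the term
    N: int  # background universe size
    ease_p: float
    bonferroni_p: float
    genes: frozenset[str] = frozenset()


def _validate(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent contingency counts k={k} n={n} K={K} N={N}")


def fisher_p(k: int, n: int, K: int, N: int) -> float:
    """Plain one-tailed Fisher exact p: P(X >= k), X ~ Hypergeom(N, K, n)."""
    _validate(k, n, K, N)
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_p(k: int, n: int, K: int, N: int) -> float:
    """EASE score: hypergeometric upper tail with k reduced by one.

    P(X >= k - 1) for k >= 1; k = 0 returns 1.  Always at least as large as
    the plain Fisher tail, so the penalisation is conservative.
    """
    _validate(k, n, K, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 2, N, K, n))


def enrich(
    gene_list: Iterable[str],
    table: AnnotationTable,
    alpha: float = 0.05,
    min_genes: int = 3,
    ease_alpha: float | None = None,
) -> list[TermResult]:
    """Terms over-represented in a gene list, Bonferroni-corrected.

    Genes outside the universe are dropped with a warning.  Every term with
    at least ``min_genes`` submitted genes is tested; the Bonferroni factor m
    is the number of terms tested.  Returns terms with bonferroni_p < alpha
    (and, when ``ease_alpha`` is given, raw EASE p < ease_alpha), sorted by
    ascending EASE p.
    """
    if not table.universe:
        raise ValueError("empty annotation universe")
    genes = set(gene_list)
    stray = genes - table.universe
    if stray:
        warnings.warn(
            f"dropping {len(stray)} genes not in the annotation universe",
            stacklevel=2,
        )
        genes -= stray
    n, N = len(genes), len(table.universe)
    candidates = []
    for term, members in sorted(table.term_to_genes.items()):
        hit = genes & members
        if len(hit) >= min_genes:
            candidates.append((term, hit, len(members)))
    m = len(candidates)
    results = []
    for term, hit, K in candidates:
        p = ease_p(len(hit), n, K, N)
        bonf = min(1.0, p * m)
        if bonf < alpha and (ease_alpha is None or p < ease_alpha):
            results.append(
                TermResult(term, len(hit), n, K, N, p, bonf, frozenset(hit))
            )
    results.sort(key=lambda r: (r.ease_p, r.term))
    return results
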