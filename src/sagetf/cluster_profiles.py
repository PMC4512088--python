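"""Fold-change matrices, Spearman/complete-linkage clustering, stage correlations.

The gene x stage matrix holds signed fold changes of mutant over wild type;
cells where neither library expressed the gene's tag carry NaN ("no
expressed tags") and are excluded pairwise from distances and correlations.
Clustering uses distance 1 - Spearman rho with complete linkage on either
axis; stage correlations report Spearman rho with a t-approximation p-value
over the genes valid in both stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.stats import spearmanr

__all__ = [
    "FoldChangeMatrix",
    "StageCorrelation",
    "Dendrogram",
    "build_matrix",
    "cluster",
    "stage_correlation",
    "plot_heatmap",
]

NO_TAGS = float("nan")


@dataclass
class FoldChangeMatrix:
    """Signed fold changes per gene (rows) and stage (columns); NaN = no tags."""

    genes: list[str]
    stages: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.stages)):
            raise ValueError("matrix shape must be (n_genes, n_stages)")

    def column(self, stage: str) -> np.ndarray:
        return self.values[:, self.stages.index(stage)]


def build_matrix(
    folds_by_stage: Mapping[str, Mapping[str, float]],
    genes: Sequence[str] | None = None,
    log2: bool = False,
) -> FoldChangeMatrix:
    """Assemble the gene x stage signed fold-change matrix.

    ``folds_by_stage`` maps stage -> (gene -> signed fold change computed
    with the zero-to-one adjustment).  Genes absent from a stage carry NaN.
    With ``log2=True``, a signed fold f is stored as sign(f) * log2(|f|).
    """
    stages = list(folds_by_stage)
    if genes is None:
        genes = sorted({g for folds in folds_by_stage.values() for g in folds})
    values = np.full((len(genes), len(stages)), NO_TAGS)
    for j, stage in enumerate(stages):
        folds = folds_by_stage[stage]
        for i, gene in enumerate(genes):
            if gene in folds:
                f = folds[gene]
                values[i, j] = math.copysign(math.log2(abs(f)), f) if log2 else f
    return FoldChangeMatrix(list(genes), stages, values)


def _spearman_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Spearman rho over pairwise-complete cells; max distance if undefined."""
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 2:
        return 2.0
    av, bv = a[mask], b[mask]
    if np.all(av == av[0]) or np.all(bv == bv[0]):
        return 2.0  # constant vector: correlation undefined
    rho = spearmanr(av, bv).statistic
    return 1.0 - float(rho)


@dataclass
class Dendrogram:
    """Complete-linkage tree: scipy linkage matrix plus ordered leaf labels."""

    labels: list[str]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        n = len(self.labels)
        Z = self.linkage_matrix

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            row = Z[i - n]
            h = row[2]
            return f"({node(int(row[0]))}:{h:.6g},{node(int(row[1]))}:{h:.6g})"

        return node(n + len(Z) - 1) + ";" if len(Z) else self.labels[0] + ";"

    def merge_heights(self) -> list[float]:
        return [float(r[2]) for r in self.linkage_matrix]


def cluster(matrix: FoldChangeMatrix, axis: str = "genes") -> Dendrogram:
    """Hierarchical clustering of genes or stages.

    Distance is 1 - Spearman correlation between value vectors over
    pairwise-complete (non-NaN) cells; linkage is complete.  Items are
    ordered lexicographically before clustering so the result does not
    depend on input order.
    """
    if axis == "genes":
        labels, data = matrix.genes, matrix.values
    elif axis == "stages":
        labels, data = matrix.stages, matrix.values.T
    else:
        raise ValueError("axis must be 'genes' or 'stages'")
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    order = np.argsort(np.array(labels, dtype=object))
    labels = [labels[i] for i in order]
    data = data[order]
    m = len(labels)
    condensed = np.array(
        [
            _spearman_distance(data[i], data[j])
            for i in range(m)
            for j in range(i + 1, m)
        ]
    )
    Z = linkage(condensed, method="complete")
    return Dendrogram(labels=labels, linkage_matrix=Z)


@dataclass(frozen=True)
class StageCorrelation:
    """Spearman correlation of two stages' fold changes over valid genes."""

    stage_a: str
    stage_b: str
    n_valid: int
    rho: float
    p_value: float

    @property
    def defined(self) -> bool:
        return self.n_valid >= 3 and not math.isnan(self.rho)


def stage_correlation(
    matrix: FoldChangeMatrix, stage_a: str, stage_b: str
) -> StageCorrelation:
    """Between-stage Spearman rho over genes valid in both stages.

    A gene is valid when both cells are non-NaN (its differential ratio is
    defined in both comparisons).  With fewer than 3 valid genes the result
    is flagged undefined (NaN statistics).
    """
    a = matrix.column(stage_a)
    b = matrix.column(stage_b)
    mask = ~np.isnan(a) & ~np.isnan(b)
    n_valid = int(mask.sum())
    if n_valid < 3:
        return StageCorrelation(stage_a, stage_b, n_valid, float("nan"), float("nan"))
    res = spearmanr(a[mask], b[mask])
    return StageCorrelation(
        stage_a, stage_b, n_valid, float(res.statistic), float(res.pvalue)
    )


def plot_heatmap(matrix: FoldChangeMatrix, path, signed_log: bool = True) -> None:
    """Fold-change heat map: green down, red up, black no change, grey no tags."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    values = matrix.values.copy()
    if signed_log:
        with np.errstate(invalid="ignore"):
            values = np.sign(values) * np.log2(np.abs(values))
    vmax = np.nanmax(np.abs(values)) or 1.0
    cmap = LinearSegmentedColormap.from_list("fold", ["green", "black", "red"])
    cmap.set_bad("grey")
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(matrix.stages), max(3.0, 0.02 * len(matrix.genes)))
    )
    ax.imshow(
        np.ma.masked_invalid(values),
        aspect="auto",
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(matrix.stages)), matrix.stages)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(matrix.genes)} genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
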