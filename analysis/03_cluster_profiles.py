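#!/usr/bin/env python
"""Fold-change matrix, hierarchical clustering, and stage correlations.

Builds the gene x stage signed fold-change matrix from the differential
tables (most significant tag per gene), clusters genes and stages by
1 - Spearman correlation with complete linkage, and reports between-stage
Spearman correlations over the genes valid in both stages.
"""

import itertools
from pathlib import Path

import pandas as pd

from sagetf import io as sio
from sagetf.cluster_profiles import build_matrix, cluster, plot_heatmap, stage_correlation

RUN = Path(__file__).resolve().parent.parent / "results" / "run"
STAGES = ["E13.5", "E15.5", "E17.5"]


def main() -> None:
    folds_by_stage = {}
    for stage in STAGES:
        df = pd.read_csv(RUN / f"difftags_{stage}.tsv", sep="\t")
        folds = {}
        best_p = {}
        for row in df.itertuples():
            if not isinstance(row.gene_ids, str) or not row.gene_ids:
                continue
            for gene in row.gene_ids.split(","):
                if gene not in best_p or row.p_value < best_p[gene]:
                    best_p[gene] = row.p_value
                    folds[gene] = row.fold_change
        folds_by_stage[stage] = folds

    matrix = build_matrix(folds_by_stage)
    sio.write_fold_matrix(matrix, RUN / "fold_matrix.tsv")
    print(f"matrix: {len(matrix.genes)} genes x {len(matrix.stages)} stages")

    (RUN / "gene_dendrogram.nwk").write_text(
        cluster(matrix, axis="genes").to_newick() + "\n"
    )
    stage_dendro = cluster(matrix, axis="stages")
    (RUN / "stage_dendrogram.nwk").write_text(stage_dendro.to_newick() + "\n")
    print("stage dendrogram:", stage_dendro.to_newick())

    for a, b in itertools.combinations(STAGES, 2):
        c = stage_correlation(matrix, a, b)
        print(
            f"{a} vs {b}: Spearman rho = {c.rho:+.2f} "
            f"(p = {c.p_value:.2g}, n_valid = {c.n_valid})"
        )

    plot_heatmap(matrix, RUN / "fold_heatmap.png")
    print("heat map written to", RUN / "fold_heatmap.png")


if __name__ == "__main__":
    main()
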