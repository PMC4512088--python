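#!/usr/bin/env python
"""Annotation-term enrichment of the anchor-positive differential genes.

Scores every annotation term carried by at least three submitted genes with
the EASE-modified one-tailed Fisher test against the full simulated gene
universe, Bonferroni-corrects over the terms tested, and writes the
significant terms plus the target gene list (top term members among the
anchor-positive genes) for the co-factor analysis.
"""

from pathlib import Path

import pandas as pd

from sagetf import io as sio
from sagetf.enrichment import enrich

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    universe = sorted(sio.read_fasta(RUN / "promoters.fa"))
    table = sio.read_annotations(RUN / "annotations.tsv", universe=universe)
    genes = sio.read_gene_list(RUN / "anchor_positive_genes.txt")
    results = enrich(genes, table, alpha=0.05, min_genes=3)
    pd.DataFrame(
        [
            {"term": r.term, "genes_in_list": r.k, "list_size": r.n,
             "genes_in_background": r.K, "background_size": r.N,
             "ease_p": r.ease_p, "bonferroni_p": r.bonferroni_p}
            for r in results
        ]
    ).to_csv(RUN / "term_enrichment.tsv", sep="\t", index=False)

    if not results:
        print("no term passed Bonferroni < 0.05")
        return
    for r in results:
        print(
            f"{r.term}: {r.k}/{r.K} genes, EASE p = {r.ease_p:.2e}, "
            f"Bonferroni p = {r.bonferroni_p:.2e}"
        )
    top = results[0]
    targets = sorted(top.genes & set(genes))
    sio.write_gene_list(targets, RUN / "target_genes.txt")
    print(f"target set: {len(targets)} genes from top term {top.term}")


if __name__ == "__main__":
    main()
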