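#!/usr/bin/env python
"""Anchor-PWM promoter scanning under phylogenetic-footprint constraints.

Builds the anchor (NR2E1-style) PWM from its binding-site sequence set,
scans the promoters of the differential genes on both strands at the 80 %
relative-score threshold, restricts predictions to retained conserved
regions (identity >= 70 %, top 10 % of the promoter by conserved length),
and writes the surviving sites plus the anchor-positive gene list.
"""

from pathlib import Path

import pandas as pd

from sagetf import io as sio
from sagetf.motif import build_pfm, footprint_filter, pwm_from_pfm, scan

RUN = Path(__file__).resolve().parent.parent / "results" / "run"
STAGES = ["E13.5", "E15.5", "E17.5"]
ANCHOR = "NR2E1"


def differential_genes() -> list[str]:
    genes: set[str] = set()
    for stage in STAGES:
        df = pd.read_csv(RUN / f"difftags_{stage}.tsv", sep="\t")
        for ids in df["gene_ids"].dropna():
            genes.update(g for g in str(ids).split(",") if g)
    return sorted(genes)


def main() -> None:
    sites_fa = sio.read_fasta(RUN / f"sites_{ANCHOR}.fa")
    pfm = build_pfm(list(sites_fa.values()))
    sio.write_pfm(pfm, RUN / f"pfm_{ANCHOR}.txt", name=ANCHOR)
    pwm = pwm_from_pfm(pfm, tf_id=ANCHOR)
    print(f"{ANCHOR} PFM: {pfm.n_sites} sites, width {pfm.length}, "
          f"consensus {pfm.consensus}")

    promoters = sio.read_fasta(RUN / "promoters.fa")
    tracks = sio.read_conservation_bed(RUN / "conservation.bed")
    genes = differential_genes()

    all_sites, positive = [], []
    for gene in genes:
        seq = promoters[gene]
        raw = scan(pwm, seq, rel_threshold=0.80, gene_id=gene)
        kept = footprint_filter(
            raw, tracks.get(gene, []), min_identity=0.70, top_fraction=0.10,
            total_length=len(seq),
        )
        all_sites.extend(kept)
        if kept:
            positive.append(gene)

    sio.write_sites_bed(all_sites, RUN / "anchor_sites.bed")
    sio.write_gene_list(positive, RUN / "anchor_positive_genes.txt")
    print(
        f"{len(genes)} differential genes scanned; "
        f"{len(all_sites)} footprinted {ANCHOR} sites on {len(positive)} genes"
    )


if __name__ == "__main__":
    main()
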