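#!/usr/bin/env python
"""Differential tag abundance per stage and cross-stage overlap.

Reads the filtered tag tables written by 01_simulate.py, compares wild type
against mutant at each stage with the Audic-Claverie exact test (P < 0.05),
maps the significant tags to genes through the canonical-tag index, and
summarises the stage overlap as a seven-region Venn partition.
"""

from pathlib import Path

import pandas as pd

from sagetf import io as sio
from sagetf.sage_diff import (
    SageLibrary,
    differential_tags,
    build_tag_index,
    filter_tags,
    map_tags_to_genes,
    venn_stats,
)
from sagetf.synthetic import LINKER_TAGS

RUN = Path(__file__).resolve().parent.parent / "results" / "run"
STAGES = ["E13.5", "E15.5", "E17.5"]


def load_library(stage: str, genotype: str) -> SageLibrary:
    records = sio.read_tag_table(RUN / f"tags_{genotype}_{stage}.tsv")
    kept = filter_tags(records, linker_tags=LINKER_TAGS).kept
    return SageLibrary.from_records(
        kept, id=f"{genotype}_{stage}", genotype=genotype, stage=stage,
        total_raw=sum(r.count for r in records),
    )


def main() -> None:
    index = build_tag_index(sio.read_fasta(RUN / "transcripts.fa"))
    gene_sets = {}
    for stage in STAGES:
        wt = load_library(stage, "Wt")
        mut = load_library(stage, "mutant")
        diffs = differential_tags(wt, mut, alpha=0.05)
        mapping = map_tags_to_genes([d.tag for d in diffs], index)
        gene_sets[stage] = mapping.genes()
        pd.DataFrame(
            [
                {
                    "tag": d.tag, "wt_count": d.count_a, "mut_count": d.count_b,
                    "p_value": d.p_value, "fold_change": d.fold_change,
                    "direction": d.direction,
                    "gene_ids": ",".join(mapping.mapped.get(d.tag, [])),
                }
                for d in diffs
            ]
        ).to_csv(RUN / f"difftags_{stage}.tsv", sep="\t", index=False)
        up = sum(d.fold_change > 0 for d in diffs)
        print(
            f"{stage}: {len(diffs)} differential tags "
            f"({up} up, {len(diffs) - up} down in the mutant), "
            f"{len(gene_sets[stage])} genes, {len(mapping.unmapped)} unmapped tags"
        )

    venn = venn_stats(*(gene_sets[s] for s in STAGES), labels=tuple(STAGES))
    sio.write_json(venn.to_dict(), RUN / "venn.json")
    for stage, pct in zip(STAGES, venn.specific_pct):
        print(f"{stage}-specific: {pct:.0f}%")
    print(
        f"triple overlap {venn.triple_pct:.1f}% of {venn.union_total} genes; "
        f"mean pairwise overlap {venn.mean_pairwise_pct:.0f}%"
    )


if __name__ == "__main__":
    main()
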