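"""Readers and writers for the pipeline's on-disk formats.

Tag tables are TSV (tag, count, mean_quality); promoters and binding-site
sets are FASTA; conservation tracks are BED with percent identity scaled to
0-1000 in the score column (0-based, half-open); predicted sites are BED6
with relative score x 1000; profiles use JASPAR PFM text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.motifs import jaspar
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster_profiles import FoldChangeMatrix
from .enrichment import AnnotationTable
from .motif import BASES, ConservedRegion, Pfm, PredictedSite
from .sage_diff import TagRecord


def write_tag_table(records: Iterable[TagRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.tag, r.count, r.quality) for r in records],
        columns=["tag", "count", "mean_quality"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | Path) -> list[TagRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str})
    return [
        TagRecord(row.tag, int(row.count), float(row.mean_quality))
        for row in df.itertuples()
    ]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_conservation_bed(
    tracks: Mapping[str, Sequence[ConservedRegion]], path: str | Path
) -> None:
    rows = []
    for name in sorted(tracks):
        for i, region in enumerate(tracks[name]):
            rows.append(
                (name, region.start, region.end, f"cons{i}",
                 int(round(region.identity * 1000)), ".")
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_conservation_bed(path: str | Path) -> dict[str, list[ConservedRegion]]:
    df = pd.read_csv(path, sep="\t", header=None)
    tracks: dict[str, list[ConservedRegion]] = {}
    for row in df.itertuples(index=False):
        tracks.setdefault(str(row[0]), []).append(
            ConservedRegion(int(row[1]), int(row[2]), float(row[4]) / 1000.0)
        )
    return tracks


def write_sites_bed(sites: Iterable[PredictedSite], path: str | Path) -> None:
    rows = [
        (
            s.gene_id,
            s.start,
            s.end,
            f"{s.tf_id}:{s.gene_id}",
            int(round(s.rel_score * 1000)),
            s.strand,
        )
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_sites_bed(path: str | Path) -> list[PredictedSite]:
    df = pd.read_csv(path, sep="\t", header=None)
    sites = []
    for row in df.itertuples(index=False):
        tf = str(row[3]).split(":", 1)[0]
        sites.append(
            PredictedSite(
                tf_id=tf,
                gene_id=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=str(row[5]),
                score=float("nan"),
                rel_score=float(row[4]) / 1000.0,
            )
        )
    return sites


def write_pfm(pfm: Pfm, path: str | Path, name: str = "motif") -> None:
    """JASPAR-style PFM text via Bio.motifs."""
    motif = motifs.Motif(
        alignment=None,
        counts={b: list(pfm.counts[i]) for i, b in enumerate(BASES)},
    )
    motif.matrix_id = name
    motif.name = name
    with open(path, "w") as fh:
        fh.write(jaspar.write([motif], "jaspar"))


def read_pfm(path: str | Path) -> Pfm:
    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
    return Pfm(counts=counts, n_sites=int(round(counts[:, 0].sum())))


def write_fold_matrix(matrix: FoldChangeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.stages)
    df.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_fold_matrix(path: str | Path) -> FoldChangeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene", na_values="NA")
    return FoldChangeMatrix(
        genes=[str(g) for g in df.index],
        stages=[str(c) for c in df.columns],
        values=df.to_numpy(float),
    )


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = [
        (term, gene)
        for term in sorted(table.term_to_genes)
        for gene in sorted(table.term_to_genes[term])
    ]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


def read_annotations(
    path: str | Path, universe: Iterable[str] | None = None
) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable.from_pairs(
        [(row.term, row.gene) for row in df.itertuples()], universe=universe
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
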