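#!/usr/bin/env python
"""Generate the synthetic study inputs.

Simulates the full study design -- two genotypes (wild type and mutant)
at three embryonic stages as LongSAGE tag libraries, promoters with planted
anchor/co-factor binding sites inside conserved blocks, conservation
tracks, binding-site sequence sets and an annotation table with one
enriched term -- and writes everything, plus the ground truth, under
results/run/.
"""

from pathlib import Path

from sagetf import io as sio
from sagetf.synthetic import (
    SimulationConfig,
    simulate_libraries,
    simulate_transcriptome,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=seed)
    transcriptome, truth = simulate_transcriptome(config)
    libraries = simulate_libraries(transcriptome, config)

    sio.write_fasta(transcriptome.promoters(), OUT / "promoters.fa")
    sio.write_fasta(transcriptome.transcripts(), OUT / "transcripts.fa")
    sio.write_conservation_bed(transcriptome.conservation, OUT / "conservation.bed")
    sio.write_annotations(transcriptome.annotations, OUT / "annotations.tsv")
    for tf, sites in transcriptome.tf_sites.items():
        sio.write_fasta(
            {f"{tf}_site{i + 1}": s for i, s in enumerate(sites)},
            OUT / f"sites_{tf}.fa",
        )
    for sim in libraries:
        sio.write_tag_table(sim.raw_records, OUT / f"tags_{sim.library.id}.tsv")
        kept = len(sim.filter_result.kept)
        print(
            f"{sim.library.id}: {sim.library.total_raw} raw tags, "
            f"{sim.library.total_useful} useful after filtering "
            f"({sim.filter_result.n_removed} records removed, {kept} kept)"
        )
    sio.write_json(
        {
            "de_genes": {g: list(v) for g, v in sorted(truth.de_genes.items())},
            "enriched_term": truth.enriched_term,
            "target_genes": truth.target_genes,
            "cofactor_genes": sorted(truth.cofactor_genes),
        },
        OUT / "ground_truth.json",
    )
    print(
        f"\n{config.n_genes} genes; {len(truth.de_genes)} spiked differential, "
        f"{len(truth.anchor_genes)} anchored promoters, "
        f"{len(truth.target_genes)} ground-truth targets "
        f"({len(truth.cofactor_genes)} with a planted proximal co-factor site)"
    )


if __name__ == "__main__":
    main()
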