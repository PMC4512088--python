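"""Ground-truth guarantees and determinism of the synthetic generator."""

import dataclasses

import numpy as np
import pytest

from sagetf import sage_diff as sd
from sagetf import synthetic as sy

RC = str.maketrans("ACGT", "TGCA")


def tiny(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_genes=80,
        library_depth=500,
        promoter_length=1001,
        footprint_block_length=300,
        enriched_term_size=12,
    )
    defaults.update(kw)
    return sy.SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"de_fraction": 1.5},
            {"promoter_length": 1000},
            {"promoter_length": 11},
            {"library_depth": 0},
            {"noise_model": "gamma"},
            {"de_fold": 0.5},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            tiny(**kw).validate() if "promoter" not in str(kw) else sy.simulate_transcriptome(tiny(**kw))


class TestTranscriptome:
    def test_every_gene_has_extractable_unique_tag(self):
        tr, _ = sy.simulate_transcriptome(tiny())
        tags = [g.tag for g in tr.genes]
        assert all(t is not None and len(t) == 21 for t in tags)
        assert len(set(tags)) == len(tags)

    def test_planted_instances_match_consensus_exactly(self):
        cfg = tiny(seed=2)
        tr, truth = sy.simulate_transcriptome(cfg)
        consensus = {
            sy.ANCHOR_TF: cfg.anchor_motif,
            sy.COFACTOR_TF: cfg.cofactor_motif,
        }
        promoters = tr.promoters()
        checked = 0
        for site in truth.planted_sites:
            if site.tf_id not in consensus:
                continue
            motif = consensus[site.tf_id]
            observed = promoters[site.gene_id][site.start : site.start + len(motif)]
            expected = motif if site.strand == "+" else motif.translate(RC)[::-1]
            assert observed == expected
            checked += 1
        assert checked > 0

    def test_planted_sites_inside_promoter_and_de_subset(self):
        cfg = tiny(seed=3)
        tr, truth = sy.simulate_transcriptome(cfg)
        for site in truth.planted_sites:
            assert 0 <= site.start < cfg.promoter_length
        assert set(truth.de_genes) <= {g.gene_id for g in tr.genes}

    def test_zero_cofactor_fraction_plants_no_cofactor(self):
        _, truth = sy.simulate_transcriptome(tiny(planted_cofactor_fraction=0.0))
        assert all(s.tf_id != sy.COFACTOR_TF for s in truth.planted_sites)

    def test_full_conservation_covers_promoter(self):
        cfg = tiny(conserved_fraction=1.0)
        tr, _ = sy.simulate_transcriptome(cfg)
        for regions in tr.conservation.values():
            assert (regions[0].start, regions[0].end) == (0, cfg.promoter_length)

    def test_conserved_blocks_straddle_identity_threshold(self):
        tr, _ = sy.simulate_transcriptome(tiny(seed=5))
        idents = [r.identity for rs in tr.conservation.values() for r in rs]
        assert any(i >= 0.7 for i in idents) and any(i < 0.7 for i in idents)

    def test_deterministic_given_seed(self):
        a, ta = sy.simulate_transcriptome(tiny(seed=9))
        b, tb = sy.simulate_transcriptome(tiny(seed=9))
        assert a.promoters() == b.promoters()
        assert a.transcripts() == b.transcripts()
        assert ta.planted_sites == tb.planted_sites
        assert ta.de_genes == tb.de_genes

    def test_promoter_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError, match="shorter than"):
            sy.simulate_transcriptome(tiny(promoter_length=11))


class TestLibraries:
    def test_null_config_has_equal_genotype_means(self):
        tr, _ = sy.simulate_transcriptome(tiny(de_fraction=0.0))
        assert all(g.mutant_mean() == g.baseline_mean for g in tr.genes)

    def test_spiked_ratio_matches_de_fold(self):
        tr, truth = sy.simulate_transcriptome(tiny(de_fraction=0.3, de_fold=5.0))
        for gene_id, (direction, fold) in truth.de_genes.items():
            g = tr.gene(gene_id)
            ratio = g.mutant_mean() / g.baseline_mean
            assert ratio == pytest.approx(5.0 if direction == "up" else 0.2)

    def test_deterministic_count_tables(self):
        cfg = tiny(seed=4)
        tr, _ = sy.simulate_transcriptome(cfg)
        libs1 = sy.simulate_libraries(tr, cfg)
        libs2 = sy.simulate_libraries(tr, cfg)
        for a, b in zip(libs1, libs2):
            assert a.library.tags == b.library.tags
            assert a.raw_records == b.raw_records

    def test_six_libraries_two_genotypes_three_stages(self):
        cfg = tiny()
        tr, _ = sy.simulate_transcriptome(cfg)
        libs = sy.simulate_libraries(tr, cfg)
        ids = [l.library.id for l in libs]
        assert len(libs) == 6
        assert {l.library.genotype for l in libs} == {"Wt", "mutant"}
        assert len(set(ids)) == 6

    def test_singleton_fraction_near_target(self):
        cfg = tiny(seed=6, n_genes=150, library_depth=3000)
        tr, _ = sy.simulate_transcriptome(cfg)
        lib = sy.simulate_libraries(tr, cfg)[0].library
        singleton_counts = sum(1 for c in lib.tags.values() if c == 1)
        frac = singleton_counts / lib.total_useful
        assert abs(frac - cfg.singleton_fraction) < 0.05

    def test_filtering_removes_contaminants(self):
        cfg = tiny(seed=8)
        tr, _ = sy.simulate_transcriptome(cfg)
        sim = sy.simulate_libraries(tr, cfg)[0]
        assert sim.filter_result.n_removed > 0
        assert sim.library.total_raw > sim.library.total_useful
        assert all("N" not in t for t in sim.library.tags)

    def test_depth_doubling_doubles_useful_tags(self):
        """Monte-Carlo: expected useful total scales linearly with depth."""
        totals = {}
        for depth in (600, 1200):
            cfg = tiny(seed=1, n_genes=60, library_depth=depth, n_stages=1,
                       promoter_length=501, contaminant_fraction=0.0)
            tr, _ = sy.simulate_transcriptome(cfg)
            obs = []
            for rep in range(100):
                rep_cfg = dataclasses.replace(cfg, seed=1000 + rep)
                obs.append(sy.simulate_libraries(tr, rep_cfg)[0].library.total_useful)
            totals[depth] = np.array(obs)
        mean_ratio = totals[1200].mean() / totals[600].mean()
        se = totals[1200].std(ddof=1) / totals[600].mean() / 10  # 100 reps
        assert abs(mean_ratio - 2.0) < 3 * se + 0.05
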