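"""PFM/PWM construction, scanning, footprint filtering and motif discovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagetf import motif as mo

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPfm:
    def test_column_tallies(self):
        pfm = mo.build_pfm(["AA", "AA"])
        assert pfm.counts[0].tolist() == [2.0, 2.0]
        assert pfm.counts.sum(axis=0).tolist() == [2.0, 2.0]

    def test_nine_site_columns_sum_to_nine(self):
        sites = ["AAGTCA", "AAGTCA", "AAGTCC", "TAGTCA"] + ["AAGTCA"] * 5
        pfm = mo.build_pfm(sites)
        assert np.all(pfm.counts.sum(axis=0) == 9)
        assert pfm.n_sites == 9

    @pytest.mark.parametrize(
        "sites", [["AA"], ["AA", "AAA"], ["AA", "AN"]]
    )
    def test_invalid_inputs_rejected(self, sites):
        with pytest.raises(ValueError):
            mo.build_pfm(sites)


class TestPwm:
    def test_uniform_column_scores_zero(self):
        pfm = mo.build_pfm(["AC", "CA", "GG", "TT"])  # first column uniform
        pwm = mo.pwm_from_pfm(pfm)
        assert pwm.weights[:, 0] == pytest.approx(np.zeros(4))

    def test_consensus_has_relative_score_one(self):
        pfm = mo.build_pfm(["ACGT", "ACGT", "ACGA"])
        pwm = mo.pwm_from_pfm(pfm)
        assert pwm.relative(pwm.score("ACGT")) == pytest.approx(1.0)
        assert pwm.max_score > pwm.min_score

    def test_zero_background_rejected(self):
        pfm = mo.build_pfm(["AC", "AC"])
        with pytest.raises(ValueError):
            mo.pwm_from_pfm(pfm, background=[0.5, 0.5, 0.0, 0.0])


@pytest.fixture(scope="module")
def pwm():
    sites = ["AAGTCAAAGTCA"] * 6 + ["AAGTCAAAGTCC", "AAGTCAAAGACA", "CAGTCAAAGTCA"]
    return mo.pwm_from_pfm(mo.build_pfm(sites), tf_id="ANCHOR")


class TestScan:
    def test_zero_threshold_reports_every_window_both_strands(self, pwm):
        seq = "ACGT" * 10
        sites = mo.scan(pwm, seq, rel_threshold=0.0)
        n_windows = len(seq) - pwm.length + 1
        assert len(sites) == 2 * n_windows

    def test_reverse_complement_mirror_symmetry(self, pwm, rng):
        seq = random_seq(rng, 300)
        fwd = mo.scan(pwm, seq, rel_threshold=0.6)
        rev = mo.scan(pwm, revcomp(seq), rel_threshold=0.6)
        mirrored = sorted(
            (len(seq) - s.end, "+" if s.strand == "-" else "-", round(s.score, 9))
            for s in rev
        )
        assert mirrored == sorted(
            (s.start, s.strand, round(s.score, 9)) for s in fwd
        )

    def test_agrees_with_biopython_pssm_rescoring(self, pwm, rng):
        """Independent cross-check against Bio.motifs log-odds scoring."""
        from Bio import motifs as bmotifs
        from Bio.Seq import Seq

        seq = random_seq(rng, 1000)
        sites_list = ["AAGTCAAAGTCA"] * 6 + [
            "AAGTCAAAGTCC", "AAGTCAAAGACA", "CAGTCAAAGTCA"
        ]
        bm = bmotifs.create([Seq(s) for s in sites_list])
        bm.pseudocounts = {b: 0.8 * 0.25 for b in "ACGT"}
        pssm = bm.pssm
        ours = {
            (s.start, s.strand): s.score
            for s in mo.scan(pwm, seq, rel_threshold=0.0)
        }
        for start in range(0, len(seq) - pwm.length + 1, 37):
            window = seq[start : start + pwm.length]
            assert ours[(start, "+")] == pytest.approx(
                pssm.calculate(Seq(window)), abs=1e-4
            )
            assert ours[(start, "-")] == pytest.approx(
                pssm.calculate(Seq(revcomp(window))), abs=1e-4
            )

    def test_n_windows_skipped_and_short_sequence_empty(self, pwm):
        assert mo.scan(pwm, "ACGTN") == []
        sites = mo.scan(pwm, "N" * 50, rel_threshold=0.0)
        assert sites == []

    def test_threshold_one_returns_only_consensus(self, pwm, rng):
        seq = random_seq(rng, 200) + "AAGTCAAAGTCA" + random_seq(rng, 200)
        sites = mo.scan(pwm, seq, rel_threshold=1.0)
        assert {(s.start, s.strand) for s in sites} == {(200, "+")}


class TestFootprint:
    SITES = [
        mo.PredictedSite("TF", "g", 110, 122, "+", 5.0, 0.9),
        mo.PredictedSite("TF", "g", 510, 522, "+", 5.0, 0.9),
        mo.PredictedSite("TF", "g", 905, 917, "-", 5.0, 0.9),
    ]

    def test_no_region_above_identity_threshold(self):
        regions = [mo.ConservedRegion(0, 1000, 0.5)]
        assert mo.footprint_filter(self.SITES, regions) == []

    def test_single_perfect_region_keeps_all(self):
        regions = [mo.ConservedRegion(0, 1000, 1.0)]
        kept = mo.footprint_filter(self.SITES, regions, top_fraction=1.0)
        assert kept == self.SITES

    def test_planted_blocks_survive_decoys_do_not(self):
        regions = [
            mo.ConservedRegion(100, 300, 0.9),   # planted block
            mo.ConservedRegion(500, 700, 0.5),   # decoy below identity
            mo.ConservedRegion(900, 1000, 0.72),  # above identity, outranked
        ]
        kept = mo.footprint_filter(
            self.SITES, regions, top_fraction=0.10, total_length=2000
        )
        assert kept == [self.SITES[0]]

    def test_monotone_in_thresholds(self):
        regions = [
            mo.ConservedRegion(0, 300, 0.95),
            mo.ConservedRegion(400, 600, 0.8),
            mo.ConservedRegion(800, 1000, 0.72),
        ]
        base = set()
        for top in (1.0, 0.5, 0.2, 0.1, 0.0):
            kept = {
                (s.start, s.strand)
                for s in mo.footprint_filter(
                    self.SITES, regions, top_fraction=top, total_length=1000
                )
            }
            if base:
                assert kept <= base_prev
            base_prev = kept
            base = base or kept or {None}
        for ident in (0.7, 0.8, 0.9, 0.99):
            kept = mo.footprint_filter(
                self.SITES, regions, min_identity=ident, top_fraction=1.0
            )
            if ident > 0.7:
                assert len(kept) <= prev_len
            prev_len = len(kept)


class TestConservationFromAlignment:
    def test_identical_sequences_single_full_region(self):
        seq = "ACGT" * 100
        regions = mo.conservation_from_alignment(seq, seq, window=50)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, len(seq))
        assert regions[0].identity == 1.0

    def test_unrelated_sequences_no_regions(self, rng):
        a = random_seq(rng, 400)
        b = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[c] for c in a)
        assert mo.conservation_from_alignment(a, b, window=50) == []

    def test_half_identical_region_confined(self, rng):
        a = random_seq(rng, 600)
        b = a[:300] + "".join(
            {"A": "C", "C": "A", "G": "T", "T": "G"}[c] for c in a[300:]
        )
        regions = mo.conservation_from_alignment(a, b, window=100)
        assert len(regions) == 1
        assert regions[0].start == 0
        assert abs(regions[0].end - 300) <= 100

    def test_gap_columns_count_as_mismatch_and_coords_ungapped(self):
        a = "ACGTACGTAC" + "--" + "ACGTACGTAC"
        b = "ACGTACGTAC" + "GG" + "ACGTACGTAC"
        regions = mo.conservation_from_alignment(a, b, window=4, threshold=0.99)
        # both flanks perfectly identical; gap block breaks them apart
        assert regions[0].start == 0
        assert regions[-1].end == 20  # ungapped first-sequence coordinates

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mo.conservation_from_alignment("ACGT", "ACG")


class TestPromoterRegion:
    @pytest.mark.parametrize(
        "tss,flank,expected",
        [(5000, 5000, (0, 10001)), (100, 5000, (0, 5101)), (42, 0, (42, 43))],
    )
    def test_interval(self, tss, flank, expected):
        assert mo.promoter_region(tss, flank) == expected


class TestDiscoverMotif:
    def test_identical_sequences_recover_common_word(self):
        seqs = ["TTTTTAAGTCAAAGTCATTTTT"] * 6
        res = mo.discover_motif(seqs, width=12, seed=0)
        assert res.consensus == "AAGTCAAAGTCA" or len(set(res.offsets)) == 1

    def test_planted_offsets_recovered(self, rng):
        consensus = "AAGTCAAAGTCA"
        seqs, offsets = [], []
        for _ in range(10):
            flank_l = int(rng.integers(20, 80))
            seq = (
                random_seq(rng, flank_l) + consensus + random_seq(rng, 40)
            )
            seqs.append(seq)
            offsets.append(flank_l)
        res = mo.discover_motif(seqs, width=len(consensus), seed=1)
        hits = sum(o == t for o, t in zip(res.offsets, offsets))
        assert hits >= 9
        assert res.consensus == consensus

    def test_deterministic_given_seed(self, rng):
        seqs = [random_seq(rng, 60) for _ in range(6)]
        a = mo.discover_motif(seqs, width=8, seed=5)
        b = mo.discover_motif(seqs, width=8, seed=5)
        assert a.offsets == b.offsets
        assert np.array_equal(a.pfm.counts, b.pfm.counts)

    def test_width_below_four_rejected(self):
        with pytest.raises(ValueError):
            mo.discover_motif(["ACGTACGT"], width=3)
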