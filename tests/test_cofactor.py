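"""Anchored co-factor statistics: proximity rules, scores, empirical null."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagetf import cofactor as co
from sagetf.motif import PredictedSite


def site(start, end, tf="B", gene="g", strand="+"):
    return PredictedSite(tf, gene, start, end, strand, 1.0, 0.9)


class TestAnchoredSites:
    def test_no_anchors_empty_and_zero_searchable(self):
        aset = co.anchored_sites([], {"B": [site(10, 20)]})
        assert aset.proximal["B"] == []
        assert aset.searchable_nt == 0

    def test_window_rule_keeps_near_drops_far(self):
        anchor = site(200, 212, tf="A")
        near = site(262, 270)    # 50 bp gap
        far = site(362, 370)     # 150 bp gap
        aset = co.anchored_sites([anchor], {"B": [near, far]}, window=100)
        assert aset.proximal["B"] == [near]

    def test_single_base_overlap_excluded(self):
        anchor = site(200, 212, tf="A")
        overlapping = site(211, 219)
        aset = co.anchored_sites([anchor], {"B": [overlapping]}, window=100)
        assert aset.proximal["B"] == []

    def test_searchable_length_arithmetic(self):
        # one 12-bp anchor at [200, 212): flanks [100, 312) minus anchor = 200
        aset = co.anchored_sites([site(200, 212, tf="A")], {}, window=100)
        assert aset.searchable_nt == 200
        # two overlapping flank windows merge before subtraction
        aset2 = co.anchored_sites(
            [site(200, 212, tf="A"), site(300, 312, tf="A")], {}, window=100
        )
        assert aset2.searchable_nt == (412 - 100) - 24


class TestFisherScore:
    def test_printed_contingency_values(self):
        assert co.fisher_score(40, 64, 172, 500) == pytest.approx(1.58e-5, rel=5e-3)
        assert co.fisher_score(41, 64, 190, 500) == pytest.approx(6.53e-5, rel=5e-3)
        assert co.fisher_score(47, 64, 248, 500) == pytest.approx(2.13e-4, rel=5e-3)

    def test_zero_target_hits_full_tail(self):
        assert co.fisher_score(0, 64, 100, 500) == 1.0

    @given(
        st.integers(1, 20),
        st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle_small_populations(self, ts, bh):
        bs = 20
        th = ts // 2
        # exhaustive tail enumeration over the hypergeometric support
        N, K, n = ts + bs, th + bh, ts
        total = sum(
            math.comb(K, k) * math.comb(N - K, n - k)
            for k in range(th, min(n, K) + 1)
        ) / math.comb(N, n)
        assert co.fisher_score(th, ts, bh, bs) == pytest.approx(total, rel=1e-12)

    def test_adding_hit_gene_never_increases_p(self):
        for th in range(0, 30):
            p1 = co.fisher_score(th, 40, 50, 300)
            p2 = co.fisher_score(th + 1, 41, 50, 300)
            assert p2 <= p1 + 1e-15


class TestZScore:
    def test_formula_transcription(self):
        # target rate twice background at target_nt = 1e4, bg rate 0.01
        t_sites, t_nt, bg_sites, bg_nt = 200, 10_000, 1000, 100_000
        p = bg_sites / bg_nt
        expected = (t_sites - p * t_nt - 0.5) / math.sqrt(t_nt * p * (1 - p))
        assert co.z_score(t_sites, t_nt, bg_sites, bg_nt) == pytest.approx(expected)
        assert expected > 10

    def test_equal_rates_near_zero(self):
        z = co.z_score(100, 10_000, 1000, 100_000)
        assert abs(z) < 0.5

    def test_zero_target_sites_negative(self):
        assert co.z_score(0, 10_000, 500, 100_000) < 0

    def test_zero_background_floored_not_infinite(self):
        z = co.z_score(10, 1000, 0, 100_000)
        assert np.isfinite(z) and z > 0

    def test_invalid_nt_rejected(self):
        with pytest.raises(ValueError):
            co.z_score(1, 0, 1, 100)


class TestEmpiricalP:
    def test_counts_strictly_more_significant(self):
        null = [5.0] * 999 + [20.0]
        p = co.empirical_p(10.0, null, better="greater")
        assert p.value == pytest.approx(0.001)
        assert str(p) == "= 0.001"

    def test_zero_reported_as_bound(self):
        p = co.empirical_p(100.0, [1.0] * 1000, better="greater")
        assert p.is_bound and str(p) == "< 0.001"

    def test_all_more_significant_is_one(self):
        p = co.empirical_p(0.5, [1.0, 2.0, 3.0], better="greater")
        assert p.value == 1.0

    def test_ties_not_counted(self):
        p = co.empirical_p(1.0, [1.0, 1.0, 2.0, 0.5], better="greater")
        assert p.n_more == 1


def _toy_world(rng, n_pool=40, n_bg=60, planted=True):
    """Hand-built site maps: anchors everywhere, co-factor near anchors in targets."""
    gene_sites = {}
    targets = [f"t{i}" for i in range(12)]
    pool = targets + [f"p{i}" for i in range(n_pool)]
    background = [f"b{i}" for i in range(n_bg)]
    for g in pool + background:
        anchors = [site(500, 512, tf="A", gene=g)]
        sites = {"A": anchors}
        is_target = g.startswith("t")
        if planted and is_target:
            sites["B"] = [site(550, 562, tf="B", gene=g)]
        elif rng.random() < 0.05:
            sites["B"] = [site(550, 562, tf="B", gene=g)]
        if rng.random() < 0.3:
            # decoy TF at a random position, sometimes proximal
            pos = int(rng.integers(0, 900))
            sites.setdefault("D", []).append(site(pos, pos + 12, tf="D", gene=g))
        gene_sites[g] = sites
    return targets, pool, background, gene_sites


class TestRunCofactorAnalysis:
    def test_planted_cofactor_enriched_and_deterministic(self, rng):
        targets, pool, background, gene_sites = _toy_world(rng)
        kwargs = dict(
            anchor_tf="A", window=100, trials=200, seed=11
        )
        a = co.run_cofactor_analysis(targets, pool, background, gene_sites, **kwargs)
        b = co.run_cofactor_analysis(targets, pool, background, gene_sites, **kwargs)
        assert [r.to_row() for r in a.results] == [r.to_row() for r in b.results]
        assert a.enriched and a.enriched[0].tf_id == "B"
        top = a.enriched[0]
        assert top.z > 10 and top.fisher < 0.01
        assert top.target_hits + top.target_nonhits == len(targets)

    def test_trials_zero_warns_and_omits_empirical(self, rng):
        targets, pool, background, gene_sites = _toy_world(rng)
        with pytest.warns(UserWarning, match="trials=0"):
            a = co.run_cofactor_analysis(
                targets, pool, background, gene_sites, anchor_tf="A", trials=0
            )
        assert all(r.empirical_p_z is None for r in a.results)
        assert a.null is None

    def test_pool_smaller_than_targets_rejected(self, rng):
        targets, pool, background, gene_sites = _toy_world(rng)
        with pytest.raises(ValueError, match="pool smaller"):
            co.run_cofactor_analysis(
                targets, targets[:3], background, gene_sites, anchor_tf="A"
            )

    def test_table_row_invariant_holds_for_all_results(self, rng):
        targets, pool, background, gene_sites = _toy_world(rng, planted=False)
        a = co.run_cofactor_analysis(
            targets, pool, background, gene_sites, anchor_tf="A",
            trials=50, seed=3,
        )
        for r in a.results:
            assert r.target_hits + r.target_nonhits == len(targets)
            assert r.bg_hits + r.bg_nonhits == len(background)
            assert 0 < r.fisher <= 1.0
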