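"""Unit and property tests for tag filtering and differential statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagetf import sage_diff as sd


def ac_lower_oracle(x, y, n1, n2):
    """Direct summation of the conditional pmf series, independent of scipy.

    p(y|x) = (n2/n1)^y (x+y)! / (x! y! (1 + n2/n1)^(x+y+1)), summed over
    0..y in log space term by term.
    """
    total = 0.0
    for k in range(y + 1):
        log_term = (
            k * (math.log(n2) - math.log(n1))
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * math.log1p(n2 / n1)
        )
        total += math.exp(log_term)
    return total


def ac_oracle(x, y, n1, n2, tail="two_sided"):
    p = min(ac_lower_oracle(x, y, n1, n2), ac_lower_oracle(y, x, n2, n1))
    return min(1.0, 2 * p) if tail == "two_sided" else p


class TestFilterTags:
    def test_empty_input(self):
        assert sd.filter_tags([]).kept == []

    @pytest.mark.parametrize(
        "record,bucket",
        [
            (sd.TagRecord("CATGNAAAAAAAAAAAAAAAA", 3, 1.0), "removed_n_base"),
            (sd.TagRecord("CATGTCGGATCCTAACGATGT", 2, 1.0), "removed_linker"),
            (sd.TagRecord("CATGAAAAAAAAAAAAAAAAA", 5, 0.98), "removed_quality"),
            (sd.TagRecord("CATGAAA", 1, 1.0), "malformed"),
        ],
    )
    def test_removal_classes(self, record, bucket):
        result = sd.filter_tags([record], linker_tags={"CATGTCGGATCCTAACGATGT"})
        assert result.kept == []
        assert getattr(result, bucket) == [record]

    def test_singletons_and_duplicated_counts_retained(self):
        records = [
            sd.TagRecord("CATG" + "A" * 17, 1, 0.995),  # singleton
            sd.TagRecord("CATG" + "C" * 17, 40, 0.999),  # duplicated-ditag counts
        ]
        assert sd.filter_tags(records).kept == records


class TestNormalize:
    def test_forced_arithmetic(self):
        assert sd.normalize_count(4, 80_000) == 5.0
        assert sd.normalize_count(0, 123) == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            sd.normalize_count(1, 0)

    @given(st.lists(st.integers(0, 500), min_size=1, max_size=30))
    def test_normalized_counts_conserve_total(self, counts):
        total = sum(counts) or 1
        assert math.isclose(
            sum(sd.normalize_count(c, total) for c in counts),
            100_000.0 * sum(counts) / total,
        )


class TestAudicClaverie:
    def test_one_sided_series_value(self):
        # x=4, y=0, equal library sizes: P(Y <= 0 | 4) = 1/32
        assert sd.audic_claverie_p(4, 0, 10_000, 10_000, "one_sided") == pytest.approx(
            1 / 32
        )

    def test_two_sided_at_mode_is_one(self):
        for x in (0, 3, 17):
            assert sd.audic_claverie_p(x, x, 5000, 5000) == pytest.approx(1.0)

    @given(
        st.integers(0, 50),
        st.integers(0, 50),
        st.sampled_from([1e3, 1e4, 1e5]),
        st.sampled_from([1e3, 1e4, 1e5]),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_oracle_agreement(self, x, y, n1, n2):
        p = sd.audic_claverie_p(x, y, n1, n2)
        assert p == sd.audic_claverie_p(y, x, n2, n1)
        assert p == pytest.approx(ac_oracle(x, y, n1, n2), rel=1e-10)
        assert 0.0 < p <= 1.0

    def test_one_sided_monotone_in_y_below_x(self):
        x, n = 30, 10_000
        ps = [sd.audic_claverie_p(x, y, n, n, "one_sided") for y in range(x + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sd.audic_claverie_p(-1, 0, 100, 100)


class TestFoldChange:
    def test_no_change_is_plus_one(self):
        assert sd.fold_change(10, 10, 5000, 5000) == 1.0

    def test_zero_adjustment_and_down_sign(self):
        # mutant absent: zero raised to one, 10-fold down in the mutant
        assert sd.fold_change(10, 0, 5000, 5000) == pytest.approx(-10.0)

    @given(
        st.integers(0, 200),
        st.integers(0, 200),
        st.integers(1000, 100_000),
        st.integers(1000, 100_000),
    )
    def test_swapping_genotypes_flips_sign(self, x, y, n1, n2):
        f = sd.fold_change(x, y, n1, n2)
        g = sd.fold_change(y, x, n2, n1)
        assert abs(f) == pytest.approx(abs(g))
        assert abs(f) >= 1.0
        if abs(abs(f) - 1.0) > 1e-12:
            assert f == pytest.approx(-g)


class TestDifferentialTags:
    def _lib(self, tags, genotype="Wt", stage="E13.5"):
        return sd.SageLibrary(
            id=f"{genotype}_{stage}", genotype=genotype, stage=stage, tags=dict(tags)
        )

    def test_identical_libraries_yield_nothing(self):
        tags = {"CATG" + "A" * 17: 50, "CATG" + "C" * 17: 3}
        assert sd.differential_tags(self._lib(tags), self._lib(tags, "mutant")) == []

    def test_unfiltered_input_rejected(self):
        bad = self._lib({"CATGN" + "A" * 16: 2})
        with pytest.raises(ValueError, match="N-base"):
            sd.differential_tags(bad, self._lib({}))

    def test_strong_spike_flagged_with_direction(self):
        base = {f"CATG{i:017d}".replace("0", "A").replace("1", "C")[:21]: 30
                for i in range(5)}
        spiked_tag = "CATG" + "G" * 17
        wt = dict(base, **{spiked_tag: 10})
        mut = dict(base, **{spiked_tag: 80})
        res = sd.differential_tags(self._lib(wt), self._lib(mut, "mutant"))
        assert [d.tag for d in res] == [spiked_tag]
        assert res[0].direction == "up" and res[0].fold_change > 4


class TestCanonicalTag:
    def test_no_nlaiii_site(self):
        assert sd.extract_canonical_tag("ACGT" * 30) is None

    def test_exact_trailing_tail(self):
        seq = "TTTT" + "CATG" + "ACGTACGTACGTACGTA"
        assert sd.extract_canonical_tag(seq) == "CATG" + "ACGTACGTACGTACGTA"

    def test_three_prime_most_qualifying_site_wins(self):
        seq = "CATG" + "A" * 20 + "CATG" + "C" * 17
        assert sd.extract_canonical_tag(seq) == "CATG" + "C" * 17

    def test_short_downstream_falls_back_upstream(self):
        # the 3'-most CATG has only 5 downstream bases and cannot host a tag
        seq = "GG" + "CATG" + "T" * 17 + "AA" + "CATG" + "GGGGG"
        assert sd.extract_canonical_tag(seq) == "CATG" + "T" * 17


class TestTagMapping:
    INDEX = {"CATG" + "A" * 17: ["g1"], "CATG" + "C" * 17: ["g2", "g3"]}

    def test_unmapped_unique_and_ambiguous(self):
        result = sd.map_tags_to_genes(
            ["CATG" + "A" * 17, "CATG" + "C" * 17, "CATG" + "G" * 17], self.INDEX
        )
        assert result.mapped["CATG" + "A" * 17] == ["g1"]
        assert result.mapped["CATG" + "C" * 17] == ["g2", "g3"]
        assert result.ambiguous == {"CATG" + "C" * 17}
        assert result.unmapped == {"CATG" + "G" * 17}

    def test_index_from_transcripts(self):
        transcripts = {
            "gA": "AA" + "CATG" + "A" * 17,
            "gB": "CC" + "CATG" + "A" * 17,
        }
        index = sd.build_tag_index(transcripts)
        assert index == {"CATG" + "A" * 17: ["gA", "gB"]}


class TestVenn:
    def test_identical_sets(self):
        s = {"a", "b", "c"}
        v = sd.venn_stats(s, set(s), set(s))
        assert v.triple_pct == 100.0
        assert v.specific_pct == (0.0, 0.0, 0.0)

    def test_disjoint_sets(self):
        v = sd.venn_stats({"a"}, {"b"}, {"c"})
        assert v.triple_pct == 0.0
        assert v.specific_pct == (100.0, 100.0, 100.0)

    @given(
        st.sets(st.integers(0, 40)),
        st.sets(st.integers(0, 40)),
        st.sets(st.integers(0, 40)),
    )
    def test_partition_reconstructs_sets(self, a, b, c):
        v = sd.venn_stats(a, b, c)
        assert v.stage_totals == (len(a), len(b), len(c))
        assert v.union_total == len(a | b | c)
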