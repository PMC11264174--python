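"""Interval arithmetic against per-bp brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvdriver.intervals import (
    assign_carriers,
    fraction_covered,
    fully_contains,
    overlap_bp,
    reciprocal_overlap,
)
from cnvdriver.models import CnvCall, GeneRecord, Locus, SampleTable


def iv(start, end, chrom="1", name="q"):
    return Locus(name, chrom, start, end)


class TestOverlapBp:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 100), (50, 150), 50),
            ((0, 100), (100, 200), 0),  # half-open abutment
            ((0, 100), (0, 100), 100),
            ((10, 20), (0, 100), 10),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(iv(*a), iv(*b)) == expected

    def test_zero_across_chromosomes(self):
        assert overlap_bp(iv(0, 100, "1"), iv(0, 100, "2")) == 0

    @given(st.integers(0, 900), st.integers(1, 100), st.integers(0, 900), st.integers(1, 100))
    def test_matches_per_bp_oracle(self, s1, l1, s2, l2):
        a, b = iv(s1, s1 + l1), iv(s2, s2 + l2)
        bp = sum(1 for x in range(1001) if s1 <= x < s1 + l1 and s2 <= x < s2 + l2)
        assert overlap_bp(a, b) == bp


class TestFractionCovered:
    def test_union_is_merged_before_measuring(self):
        others = [iv(0, 50), iv(25, 75)]
        assert fraction_covered(iv(0, 100), others) == pytest.approx(0.75)

    def test_no_others_gives_zero(self):
        assert fraction_covered(iv(0, 100), []) == 0.0

    def test_zero_length_query_rejected(self):
        from types import SimpleNamespace

        q = SimpleNamespace(chrom="1", start=5, end=5)
        with pytest.raises(ValueError, match="zero-length"):
            fraction_covered(q, [])

    def test_random_configurations_match_bitmap_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            qs = int(rng.integers(0, 500))
            qe = qs + int(rng.integers(1, 500))
            others = []
            bitmap = np.zeros(1100, dtype=bool)
            for _k in range(rng.integers(0, 8)):
                s = int(rng.integers(0, 1000))
                e = s + int(rng.integers(1, 100))
                chrom = "1" if rng.random() < 0.8 else "2"
                others.append(iv(s, e, chrom, f"o{_k}"))
                if chrom == "1":
                    bitmap[s:e] = True
            expect = bitmap[qs:qe].sum() / (qe - qs)
            got = fraction_covered(iv(qs, qe), others)
            assert got == pytest.approx(expect, abs=1e-12)

    @given(
        st.lists(st.tuples(st.integers(0, 200), st.integers(1, 60)), max_size=6),
        st.tuples(st.integers(0, 200), st.integers(1, 60)),
    )
    def test_monotone_as_intervals_are_added(self, others, extra):
        q = iv(50, 150)
        base = [iv(s, s + l, name=f"o{i}") for i, (s, l) in enumerate(others)]
        before = fraction_covered(q, base)
        after = fraction_covered(q, base + [iv(extra[0], extra[0] + extra[1], name="x")])
        assert after >= before

    def test_reciprocal_mode_is_pairwise_max(self):
        q = iv(0, 100)
        others = [iv(0, 50), iv(40, 140)]
        # [0,50): min(50/100, 50/50)=0.5 ; [40,140): min(60/100, 60/100)=0.6
        assert fraction_covered(q, others, reciprocal=True) == pytest.approx(0.6)
        assert reciprocal_overlap(q, others[0]) == pytest.approx(0.5)


class TestFullyContains:
    region = Locus("r", "1", 0, 1000)

    def gene(self, s, e, chrom="1"):
        return GeneRecord("g", chrom, s, e, 0.5, 0.5)

    def test_inside(self):
        assert fully_contains(self.region, self.gene(10, 20))

    def test_partial_overlap_is_not_containment(self):
        assert not fully_contains(self.region, self.gene(990, 1010))

    def test_exact_bounds_count_as_contained(self):
        assert fully_contains(self.region, self.gene(0, 1000))

    def test_other_chromosome(self):
        assert not fully_contains(self.region, self.gene(10, 20, chrom="2"))


class TestAssignCarriers:
    def test_del_sets_del_and_pooled_flags_only(self, small_loci, small_samples, small_cnvs):
        m = assign_carriers(small_cnvs, small_loci, small_samples)
        assert m.is_carrier("16p11.2", "case0", "DEL")
        assert m.is_carrier("16p11.2", "case0")
        assert not m.is_carrier("16p11.2", "case0", "DUP")

    def test_multiple_cnvs_count_once(self, small_loci, small_samples, small_cnvs):
        m = assign_carriers(small_cnvs, small_loci, small_samples)
        a, b, c, d = m.counts("16p11.2", "DEL")
        assert (a, b, c, d) == (1, 3, 0, 4)

    def test_unknown_sample_rejected(self, small_loci, small_samples):
        stray = [CnvCall("16", 29_600_000, 29_700_000, "DEL", "ghost")]
        with pytest.raises(ValueError, match="ghost"):
            assign_carriers(stray, small_loci, small_samples)

    def test_min_overlap_threshold_applies(self, small_samples):
        loci = [Locus("L", "1", 100, 200)]
        cnvs = [CnvCall("1", 150, 250, "DEL", "case0")]
        m = assign_carriers(cnvs, loci, small_samples, min_overlap_bp=50)
        assert m.is_carrier("L", "case0")
        m = assign_carriers(cnvs, loci, small_samples, min_overlap_bp=51)
        assert not m.is_carrier("L", "case0")

    def test_matches_quadratic_oracle_and_order_invariance(self):
        rng = np.random.default_rng(7)
        samples = SampleTable(
            {f"case{i}": "case" for i in range(20)} | {f"ctrl{i}": "control" for i in range(20)}
        )
        ids = list(samples.status)
        loci = [
            Locus(f"L{i}", str(rng.integers(1, 4)), s := int(rng.integers(0, 5000)), s + int(rng.integers(100, 2000)))
            for i in range(15)
        ]
        cnvs = [
            CnvCall(str(rng.integers(1, 4)), s := int(rng.integers(0, 6000)), s + int(rng.integers(50, 1500)),
                    "DEL" if rng.random() < 0.5 else "DUP", ids[rng.integers(0, len(ids))])
            for _ in range(200)
        ]
        m = assign_carriers(cnvs, loci, samples)
        # quadratic all-pairs oracle
        for locus in loci:
            for key in ("DEL", "DUP"):
                expect = {
                    c.sample_id
                    for c in cnvs
                    if c.cnv_type == key
                    and c.chrom == locus.chrom
                    and min(c.end, locus.end) - max(c.start, locus.start) >= 1
                }
                assert m.carriers[(locus.locus_id, key)] == expect
        m_rev = assign_carriers(list(reversed(cnvs)), loci, samples)
        assert m.carriers == m_rev.carriers
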