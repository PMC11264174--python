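"""Fisher exact test against a hypergeometric enumeration oracle, Bonferroni
arithmetic, the region scan, and novelty classification."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from cnvdriver.association import (
    bonferroni_threshold,
    classify_novelty,
    fisher_exact_two_sided,
    region_scan,
    sample_odds_ratio,
)
from cnvdriver.models import CnvCall, Locus, SampleTable


def enumeration_p(a, b, c, d):
    """Independent oracle: sum hypergeometric pmf over all tables with the
    observed margins whose probability is <= that of the observed table."""
    row1, col1, total = a + b, a + c, a + b + c + d
    avals = np.arange(max(0, col1 - (total - row1)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(avals, total, col1, row1)
    p_obs = hypergeom.pmf(a, total, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_two_extreme_tables_example(self):
        # (5,5,0,10): the two most extreme tables each have pmf 252/15504
        p, orat = fisher_exact_two_sided(5, 5, 0, 10)
        assert p == pytest.approx(2 * 252 / 15504, abs=1e-12)
        assert p == pytest.approx(0.03250774, abs=1e-7)

    def test_empty_carrier_margin(self):
        p, orat = fisher_exact_two_sided(0, 10, 0, 10)
        assert p == 1.0
        assert math.isnan(orat)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(2000):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
            p, _ = fisher_exact_two_sided(a, b, c, d)
            assert abs(p - enumeration_p(a, b, c, d)) < 1e-12, (a, b, c, d)

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            p1, _ = fisher_exact_two_sided(a, b, c, d)
            p2, _ = fisher_exact_two_sided(d, c, b, a)  # swap rows AND columns
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    @pytest.mark.parametrize(
        "table, expect",
        [
            ((2, 3, 4, 5), 2 * 5 / (3 * 4)),
            ((0, 3, 4, 5), 0.5 * 5.5 / (3.5 * 4.5)),  # Haldane on a single zero cell
            ((2, 0, 4, 5), 2.5 * 5.5 / (0.5 * 4.5)),
        ],
    )
    def test_odds_ratio_policy(self, table, expect):
        assert sample_odds_ratio(*table) == pytest.approx(expect)

    def test_odds_ratio_nan_when_margin_empty(self):
        assert math.isnan(sample_odds_ratio(0, 5, 0, 5))
        assert math.isnan(sample_odds_ratio(5, 0, 5, 0))


class TestBonferroni:
    def test_printed_thresholds_reproduced(self):
        assert bonferroni_threshold(0.05, 2273) == pytest.approx(2.1997e-5, rel=1e-4)
        assert bonferroni_threshold(0.05, 40838) == pytest.approx(1.2244e-6, rel=1e-4)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)


class TestRegionScan:
    def _cohort(self, n_case_carriers, n_ctrl_carriers, n=40):
        status = {f"case{i}": "case" for i in range(n)}
        status.update({f"ctrl{i}": "control" for i in range(n)})
        samples = SampleTable(status)
        locus = Locus("L1", "1", 1000, 2000)
        cnvs = [CnvCall("1", 900, 2100, "DEL", f"case{i}") for i in range(n_case_carriers)]
        cnvs += [CnvCall("1", 900, 2100, "DEL", f"ctrl{i}") for i in range(n_ctrl_carriers)]
        return cnvs, [locus], samples

    def test_single_locus_threshold_is_alpha(self):
        cnvs, loci, samples = self._cohort(10, 1)
        scan = region_scan(cnvs, loci, samples, alpha=0.05)
        assert scan.pooled[0].bonferroni_threshold == 0.05

    def test_counts_and_flags(self):
        cnvs, loci, samples = self._cohort(12, 1)
        res = region_scan(cnvs, loci, samples).pooled[0]
        assert (res.a, res.b, res.c, res.d) == (12, 28, 1, 39)
        assert res.nominal and res.significant
        assert res.odds_ratio > 1

    def test_significant_subset_of_nominal(self):
        rng = np.random.default_rng(5)
        status = {f"case{i}": "case" for i in range(100)}
        status.update({f"ctrl{i}": "control" for i in range(100)})
        samples = SampleTable(status)
        ids = list(status)
        loci = [Locus(f"L{i}", "1", i * 10_000, i * 10_000 + 5_000) for i in range(20)]
        cnvs = [
            CnvCall("1", l.start, l.end, "DEL", ids[j])
            for l in loci
            for j in rng.choice(200, size=rng.integers(0, 20), replace=False)
        ]
        scan = region_scan(cnvs, loci, samples)
        sig = {r.unit_id for r in scan.significant}
        nom = {r.unit_id for r in scan.nominal}
        assert sig <= nom

    def test_type_labels_follow_case_excess(self):
        cnvs, loci, samples = self._cohort(10, 1)
        cnvs += [CnvCall("1", 900, 2100, "DUP", "ctrl5"), CnvCall("1", 900, 2100, "DUP", "ctrl6")]
        scan = region_scan(cnvs, loci, samples)
        assert scan.type_labels["L1"] == "deletion"

    def test_zero_cases_rejected(self):
        samples = SampleTable({"c1": "control"})
        with pytest.raises(ValueError):
            region_scan([], [Locus("L", "1", 0, 10)], samples)


class TestClassifyNovelty:
    ref = [Locus("ref1", "1", 1000, 2000), Locus("ref2", "2", 0, 500)]

    def test_identical_region_is_known(self):
        calls = classify_novelty([Locus("q", "1", 1000, 2000)], self.ref)
        assert calls[0].status == "known"
        assert calls[0].matched_reference_ids == ("ref1",)

    def test_containing_region_with_low_reciprocal_overlap_expands_boundary(self):
        calls = classify_novelty([Locus("q", "1", 0, 10_000)], self.ref)
        assert calls[0].status == "boundary_expansion"

    def test_chromosome_absent_from_reference_is_novel(self):
        calls = classify_novelty([Locus("q", "7", 1000, 2000)], self.ref)
        assert calls[0].status == "novel"
        assert calls[0].matched_reference_ids == ()
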