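"""Rare-CNV filtering and per-gene burden testing."""

import math

import numpy as np
import pytest

from cnvdriver.burden import RarityConfig, filter_rare, gene_burden_scan
from cnvdriver.catalog import QdsgCatalog, QdsgEntry
from cnvdriver.models import CnvCall, GeneRecord, SampleTable


def common(start, end, af, cnv_type="DEL", chrom="1"):
    return CnvCall(chrom, start, end, cnv_type, "popref", af)


class TestFilterRare:
    def test_fully_covered_by_common_del_removed(self):
        cnv = CnvCall("1", 100, 200, "DEL", "s1")
        assert filter_rare([cnv], [common(50, 250, 0.5)]) == []

    def test_exactly_half_covered_retained(self):
        cnv = CnvCall("1", 100, 200, "DEL", "s1")
        kept = filter_rare([cnv], [common(100, 150, 0.5)])
        assert kept == [cnv]

    def test_just_over_half_removed(self):
        cnv = CnvCall("1", 100, 200, "DEL", "s1")
        assert filter_rare([cnv], [common(100, 151, 0.5)]) == []

    def test_low_frequency_variants_do_not_mask(self):
        cnv = CnvCall("1", 100, 200, "DEL", "s1")
        kept = filter_rare([cnv], [common(50, 250, 0.0005)])
        assert kept == [cnv]

    def test_masking_is_type_matched(self):
        cnv = CnvCall("1", 100, 200, "DEL", "s1")
        kept = filter_rare([cnv], [common(50, 250, 0.5, cnv_type="DUP")])
        assert kept == [cnv]

    def test_common_variant_without_af_rejected(self):
        cnv = CnvCall("1", 100, 200, "DEL", "s1")
        with pytest.raises(ValueError, match="allele frequency"):
            filter_rare([cnv], [CnvCall("1", 0, 300, "DEL", "popref")])

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(21)
        cnvs = [
            CnvCall("1", s := int(rng.integers(0, 5000)), s + int(rng.integers(50, 500)),
                    "DEL" if rng.random() < 0.5 else "DUP", f"s{i}")
            for i in range(100)
        ]
        commons = [
            common(s := int(rng.integers(0, 5000)), s + int(rng.integers(50, 800)),
                   float(rng.uniform(0, 0.2)), "DEL" if rng.random() < 0.5 else "DUP")
            for _ in range(40)
        ]
        kept = filter_rare(cnvs, commons)
        assert set(kept) <= set(cnvs)
        assert filter_rare(kept, commons) == kept

    def test_matches_per_bp_bitmap_oracle(self):
        rng = np.random.default_rng(8)
        config = RarityConfig()
        for _ in range(300):
            s = int(rng.integers(0, 900))
            cnv = CnvCall("1", s, s + int(rng.integers(10, 100)), "DEL", "s1")
            commons, bitmap = [], np.zeros(1100, dtype=bool)
            for _k in range(rng.integers(0, 6)):
                cs = int(rng.integers(0, 1000))
                ce = cs + int(rng.integers(10, 120))
                af = float(rng.choice([0.0001, 0.01, 0.3]))
                commons.append(common(cs, ce, af))
                if af >= config.af_threshold:
                    bitmap[cs:ce] = True
            frac = bitmap[cnv.start:cnv.end].sum() / cnv.length
            expect = [cnv] if frac <= config.max_common_overlap else []
            assert filter_rare([cnv], commons, config) == expect


def make_cohort(n_cases=60, n_controls=60):
    status = {f"case{i}": "case" for i in range(n_cases)}
    status.update({f"ctrl{i}": "control" for i in range(n_controls)})
    return SampleTable(status)


GENES = [
    GeneRecord("HIA", "1", 1_000, 2_000, 0.9, 0.1),
    GeneRecord("TSA", "1", 5_000, 6_000, 0.1, 0.995),
    GeneRecord("BOTH", "2", 1_000, 2_000, 0.9, 0.995),
]
CATALOG = QdsgCatalog(
    [QdsgEntry("HIA", "r1", "HI"), QdsgEntry("TSA", "r1", "TS"), QdsgEntry("BOTH", "r2", "bHITS")]
)


class TestGeneBurdenScan:
    def test_tier_thresholds_reproduce_alpha_over_tier_size(self):
        entries = (
            [QdsgEntry(f"h{i}", "r", "HI") for i in range(258)]
            + [QdsgEntry(f"t{i}", "r", "TS") for i in range(6)]
            + [QdsgEntry(f"b{i}", "r", "bHITS") for i in range(30)]
        )
        cat = QdsgCatalog(entries)
        genes = [
            GeneRecord(e.gene_id, "1", 1000 * i, 1000 * i + 500, 0.9, 0.99)
            for i, e in enumerate(entries)
        ]
        results = gene_burden_scan(cat, [], [], [], genes, make_cohort(), alpha=0.05)
        by_id = {r.unit_id: r for r in results}
        assert by_id["h0"].bonferroni_threshold == pytest.approx(0.05 / 258)
        assert by_id["t0"].bonferroni_threshold == pytest.approx(0.05 / 6)
        assert by_id["b0"].bonferroni_threshold == pytest.approx(0.05 / 30)
        assert by_id["h0"].bonferroni_threshold == pytest.approx(1.937984e-4, rel=1e-6)

    def test_zero_carrier_gene_p1_or_na(self):
        results = gene_burden_scan(CATALOG, [], [], [], GENES, make_cohort())
        primary = next(r for r in results if r.unit_id == "HIA")
        assert primary.p_value == 1.0
        assert math.isnan(primary.odds_ratio)

    def test_tier_matched_cnv_classes(self):
        samples = make_cohort(4, 4)
        case_del = [CnvCall("1", 900, 2100, "DEL", "case0")]
        case_dup = [CnvCall("1", 4_900, 6_100, "DUP", "case1"),
                    CnvCall("2", 900, 2100, "DUP", "case2")]
        ctrl = [CnvCall("2", 900, 2100, "DEL", "ctrl0")]
        results = {r.unit_id: r for r in gene_burden_scan(
            CATALOG, case_del, case_dup, ctrl, GENES, samples)}
        assert results["HIA"].a == 1  # HI gene counts the case deletion
        assert results["TSA"].a == 1  # TS gene counts the case duplication
        assert results["BOTH"].a == 1 and results["BOTH"].c == 1  # pooled classes
        # per-class results are emitted alongside
        assert results["BOTH|DEL"].c == 1 and results["BOTH|DUP"].a == 1

    def test_catalog_gene_missing_from_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            gene_burden_scan(CATALOG, [], [], [], GENES[:2], make_cohort())

    def test_planted_case_excess_detected(self):
        rng = np.random.default_rng(30)
        samples = make_cohort(400, 250)
        f_ctrl, odds = 0.02, 8.0
        f_case = odds * f_ctrl / (1 - f_ctrl + odds * f_ctrl)
        case_del = [
            CnvCall("1", 900, 2100, "DEL", s)
            for s in samples.case_ids
            if rng.random() < f_case
        ]
        ctrl = [
            CnvCall("1", 900, 2100, "DEL", s)
            for s in samples.control_ids
            if rng.random() < f_ctrl
        ]
        results = {r.unit_id: r for r in gene_burden_scan(
            CATALOG, case_del, [], ctrl, GENES, samples)}
        assert results["HIA"].significant
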