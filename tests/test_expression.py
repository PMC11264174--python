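"""Expression normalization, top-percentile flagging and qDSG enrichment."""

import numpy as np
import pandas as pd
import pytest

from cnvdriver.catalog import QdsgCatalog, QdsgEntry
from cnvdriver.expression import (
    STAGES,
    expression_enrichment,
    persistent_high_expression,
    size_factors,
    top_percentile_flags,
    variance_stabilize,
)
from cnvdriver.simulate import generate_expression


def meta(samples, stage="fetal", region="neocortex"):
    return pd.DataFrame(
        {"stage": stage, "brain_region": region}, index=pd.Index(samples, name="sample_id")
    )


class TestVarianceStabilize:
    def test_global_depth_factor_removed(self):
        counts = pd.DataFrame(
            {"s1": [10, 100, 40, 7], "s2": [20, 200, 80, 14]},
            index=["g1", "g2", "g3", "g4"],
        )
        vst = variance_stabilize(counts)
        assert np.allclose(vst["s1"], vst["s2"])

    def test_zero_count_transforms_to_zero(self):
        counts = pd.DataFrame({"s1": [0, 10, 10], "s2": [0, 10, 10]}, index=list("abc"))
        vst = variance_stabilize(counts)
        assert vst.loc["a"].eq(0.0).all()

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            variance_stabilize(counts)

    def test_flattens_variance_mean_relationship(self):
        rng = np.random.default_rng(5)
        means = np.geomspace(5, 5000, 60)
        d = 0.2
        n_param = 1 / d
        raw = np.column_stack([
            rng.negative_binomial(n_param, n_param / (n_param + means)) for _ in range(30)
        ])
        counts = pd.DataFrame(raw, index=[f"g{i}" for i in range(60)],
                              columns=[f"s{i}" for i in range(30)])
        vst = variance_stabilize(counts)
        def slope(frame):
            mu = frame.mean(axis=1)
            var = frame.var(axis=1)
            keep = (mu > 0) & (var > 0)
            return np.polyfit(np.log10(mu[keep]), np.log10(var[keep]), 1)[0]
        assert slope(vst) < 0.5 * slope(counts)


class TestTopPercentileFlags:
    def test_five_of_hundred_absent_ties(self):
        counts = pd.DataFrame(
            {"s1": np.arange(1, 101), "s2": np.arange(1, 101)},
            index=[f"g{i}" for i in range(100)],
        )
        flags = top_percentile_flags(np.log2(counts + 1), meta(["s1", "s2"]))
        assert int(flags.iloc[:, 0].sum()) == 5

    def test_all_identical_all_flagged(self):
        counts = pd.DataFrame({"s1": [7.0] * 20, "s2": [7.0] * 20}, index=[f"g{i}" for i in range(20)])
        flags = top_percentile_flags(counts, meta(["s1", "s2"]))
        assert flags.iloc[:, 0].all()

    def test_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(
            rng.gamma(2, 10, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(4)],
        )
        m = meta(vals.columns)
        f1 = top_percentile_flags(vals, m)
        f2 = top_percentile_flags(vals * 3.7 + 1.0, m)  # monotone map
        assert f1.equals(f2)

    def test_planted_top_set_recovered_per_stratum(self):
        strata = [(s, r) for s in STAGES for r in ("neocortex", "cerebellum")]
        planted = [f"G{i + 1:05d}" for i in range(10)]  # 5% of 200
        em = generate_expression(200, strata, planted, seed=13)
        flags = top_percentile_flags(variance_stabilize(em.counts), em.sample_meta)
        for col in flags.columns:
            flagged = set(flags.index[flags[col]])
            overlap = len(flagged & set(planted)) / len(planted)
            assert overlap >= 0.95


class TestExpressionEnrichment:
    catalog = QdsgCatalog([QdsgEntry(f"G{i + 1:05d}", "r1", "HI") for i in range(10)])

    def test_planted_design_is_enriched(self):
        em = generate_expression(200, [("fetal", "neocortex")], self.catalog.genes(), seed=3)
        flags = top_percentile_flags(variance_stabilize(em.counts), em.sample_meta)
        res = expression_enrichment(self.catalog, flags)
        assert len(res) == 1
        assert res[0].odds_ratio > 1 and res[0].p_value < 1e-6

    def test_disjoint_flags_give_depletion(self):
        genes = [f"G{i + 1:05d}" for i in range(40)]
        flags = pd.DataFrame({("fetal", "neocortex"): [g not in self.catalog.genes() and i < 12
                                                       for i, g in enumerate(genes)]},
                             index=genes)
        flags.columns = pd.MultiIndex.from_tuples(flags.columns, names=["stage", "brain_region"])
        res = expression_enrichment(self.catalog, flags)
        assert res[0].a == 0 and res[0].odds_ratio < 1


class TestPersistentHighExpression:
    def make_flags(self, data, regions=("neocortex",)):
        genes = sorted(data)
        cols = [(s, r) for s in STAGES for r in regions]
        frame = pd.DataFrame(
            {c: [c in data[g] for g in genes] for c in cols}, index=genes
        )
        frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["stage", "brain_region"])
        return frame

    def test_gene_flagged_at_every_stage_included(self):
        flags = self.make_flags({
            "gA": {(s, "neocortex") for s in STAGES},
            "gB": {(s, "neocortex") for s in STAGES if s != "adulthood"},
        })
        assert persistent_high_expression(flags) == ["gA"]

    def test_equals_set_intersection_oracle(self):
        rng = np.random.default_rng(17)
        regions = ("neocortex", "amygdala")
        genes = [f"g{i}" for i in range(30)]
        data = {
            g: {(s, r) for s in STAGES for r in regions if rng.random() < 0.7}
            for g in genes
        }
        flags = self.make_flags(data, regions)
        got = set(persistent_high_expression(flags))
        oracle = {
            g for g in genes
            if any(all((s, r) in data[g] for s in STAGES) for r in regions)
        }
        assert got == oracle
        got_all = set(persistent_high_expression(flags, all_regions=True))
        oracle_all = {
            g for g in genes
            if all(all((s, r) in data[g] for s in STAGES) for r in regions)
        }
        assert got_all == oracle_all
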