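"""The synthetic-data generators: planted structure, determinism, edge cases."""

import numpy as np
import pytest

from cnvdriver.intervals import overlap_bp
from cnvdriver.models import Locus
from cnvdriver.simulate import (
    CohortSpec,
    FamilySpec,
    case_carrier_freq,
    default_locus_grid,
    generate_cohort,
    generate_expression,
    generate_gene_annotation,
    generate_multiplex_families,
    generate_phenotypes,
)


class TestOddsTransform:
    def test_closed_form(self):
        # f=0.01, OR=10 -> 0.1/(0.99+0.1)
        assert case_carrier_freq(0.01, 10) == pytest.approx(0.1 / 1.09)
        assert case_carrier_freq(0.01, 10) == pytest.approx(0.0917431, abs=1e-6)

    def test_or_one_is_identity(self):
        for f in (0.001, 0.3, 0.9):
            assert case_carrier_freq(f, 1.0) == pytest.approx(f)

    def test_monte_carlo_agreement(self):
        loci = [Locus("L1", "1", 1_000_000, 2_000_000)]
        spec = CohortSpec(
            n_cases=100_000, n_controls=1000, loci=loci,
            risk_effects={"L1": (0.01, 10.0)}, background_cnv_rate=0.0, seed=5,
        )
        calls, samples = generate_cohort(spec)
        case_carriers = {c.sample_id for c in calls if c.sample_id.startswith("case")}
        f_hat = len(case_carriers) / spec.n_cases
        expect = case_carrier_freq(0.01, 10.0)
        assert f_hat == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / 1e5))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            case_carrier_freq(0.0, 2.0)
        with pytest.raises(ValueError):
            case_carrier_freq(0.5, -1.0)


class TestGenerateCohort:
    loci = [Locus("L1", "1", 1_000_000, 2_000_000), Locus("L2", "2", 0, 500_000)]

    def test_fixed_seed_reproduces_identical_output(self):
        spec = CohortSpec(200, 200, self.loci, {"L1": (0.05, 3.0)}, seed=8)
        out1 = generate_cohort(spec)
        out2 = generate_cohort(spec)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_planted_carriers_fully_cover_locus(self):
        spec = CohortSpec(500, 500, self.loci, {"L1": (0.05, 2.0)},
                          background_cnv_rate=0.0, seed=1)
        calls, _ = generate_cohort(spec)
        for c in calls:
            assert (c.chrom, c.start, c.end) == ("1", 1_000_000, 2_000_000)

    def test_background_never_intersects_risk_loci(self):
        spec = CohortSpec(300, 300, self.loci, {"L1": (0.05, 2.0)},
                          background_cnv_rate=2.0, seed=2)
        calls, _ = generate_cohort(spec)
        background = [c for c in calls if (c.chrom, c.start, c.end) != ("1", 1_000_000, 2_000_000)]
        assert background  # rate 2.0 over 600 samples must place events
        for c in background:
            for locus in self.loci:
                assert overlap_bp(c, locus) == 0

    def test_zero_cases_gives_control_only_cohort(self):
        spec = CohortSpec(0, 50, self.loci, {"L1": (0.1, 2.0)}, seed=3)
        calls, samples = generate_cohort(spec)
        assert samples.n_cases == 0 and samples.n_controls == 50
        assert all(c.sample_id.startswith("ctrl") for c in calls)

    def test_unknown_risk_locus_rejected(self):
        with pytest.raises(ValueError, match="unknown locus"):
            CohortSpec(10, 10, self.loci, {"nope": (0.1, 2.0)})


class TestGenerateGeneAnnotation:
    regions = default_locus_grid(5)

    def test_exact_tier_allocation(self):
        genes = generate_gene_annotation(100, self.regions, 0.1, 0.0, 0.0, seed=1)
        n_hi = sum(1 for g in genes if g.phi >= 0.84 and g.pts < 0.993)
        assert n_hi == 10

    def test_zero_fractions_give_zero_qdsgs(self):
        genes = generate_gene_annotation(50, self.regions, 0.0, 0.0, 0.0, seed=1)
        assert all(g.phi < 0.84 and g.pts < 0.993 for g in genes)

    def test_cds_inside_parent_region_and_disjoint(self):
        genes = generate_gene_annotation(60, self.regions, 0.2, 0.1, 0.1, seed=6)
        by_region: dict[str, list] = {}
        for g in genes:
            region = next(
                r for r in self.regions
                if r.chrom == g.chrom and r.start <= g.cds_start and g.cds_end <= r.end
            )
            by_region.setdefault(region.locus_id, []).append(g)
        for genes_in in by_region.values():
            spans = sorted((g.cds_start, g.cds_end) for g in genes_in)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_excess_fractions_rejected(self):
        with pytest.raises(ValueError):
            generate_gene_annotation(10, self.regions, 0.6, 0.3, 0.2, seed=0)


class TestGenerateFamilies:
    genes = generate_gene_annotation(20, default_locus_grid(4), 1.0, 0.0, 0.0, seed=11)

    def test_deterministic(self):
        spec = FamilySpec(50, transmission_prob=0.7, seed=10)
        assert generate_multiplex_families(spec, self.genes) == generate_multiplex_families(spec, self.genes)

    def test_full_transmission(self):
        from cnvdriver.tdt import count_transmissions

        spec = FamilySpec(80, transmission_prob=1.0, carrier_parent_freq=0.5, seed=12)
        ped, calls = generate_multiplex_families(spec, self.genes)
        c = count_transmissions(ped, calls, [g.gene_id for g in self.genes], self.genes)
        assert c.opportunities > 0
        assert c.transmitted == c.opportunities

    def test_empty_target_genes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_multiplex_families(FamilySpec(5), [])


class TestGenerateExpression:
    def test_flag_count_in_single_stratum(self):
        from cnvdriver.expression import top_percentile_flags, variance_stabilize

        em = generate_expression(100, [("fetal", "neocortex")], [], seed=1)
        flags = top_percentile_flags(variance_stabilize(em.counts), em.sample_meta)
        assert int(flags.iloc[:, 0].sum()) == 5

    def test_zero_dispersion_gives_deterministic_ties(self):
        em = generate_expression(10, [("fetal", "neocortex")], [], nb_mean=40,
                                 nb_dispersion=0.0, seed=1)
        # all counts equal round(mean) per gene across samples
        assert (em.counts.nunique(axis=1) == 1).all()

    def test_counts_non_negative_integers(self):
        em = generate_expression(50, [("fetal", "neocortex"), ("adulthood", "amygdala")], [], seed=9)
        assert (em.counts.values >= 0).all()
        assert em.counts.values.dtype.kind == "i"

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_expression(10, [("fetal", "neocortex")], ["NOPE"], seed=1)


class TestGeneratePhenotypes:
    def test_effect_carriers_draw_at_effect_incidence(self):
        patients = [f"p{i}" for i in range(2000)]
        carriers = {"G1": patients[:1000]}
        tab = generate_phenotypes(carriers, patients, {("G1", "HP:T"): 0.9},
                                  {"HP:T": 0.05}, seed=19)
        inc_carr = sum(tab.has_term(p, "HP:T") for p in patients[:1000]) / 1000
        inc_rest = sum(tab.has_term(p, "HP:T") for p in patients[1000:]) / 1000
        assert inc_carr == pytest.approx(0.9, abs=0.03)
        assert inc_rest == pytest.approx(0.05, abs=0.03)

    def test_deterministic(self):
        patients = [f"p{i}" for i in range(50)]
        args = ({"G1": patients[:10]}, patients, {("G1", "HP:T"): 0.5}, {"HP:T": 0.1})
        assert generate_phenotypes(*args, seed=3) == generate_phenotypes(*args, seed=3)

    def test_bad_incidence_rejected(self):
        with pytest.raises(ValueError):
            generate_phenotypes({}, [], {("G", "T"): 1.5}, {}, seed=0)
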