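"""Calibration, agreement and power studies over the synthetic generators.

These are the package's self-validation experiments: exact-test agreement
with independent enumeration oracles, type-I calibration of the scans on
all-null cohorts, and power to recover planted effects at the study sizes
the pipeline is designed for. The analysis drivers, the test suite and the
acceptance script all run these same functions.

Study sizes are chosen to make each check informative yet quick on one
CPU: calibration uses polymorphic null loci (carrier frequency 0.1) so the
discrete null distribution of the exact test is fine-grained — at rare-CNV
frequencies the exact test's conservatism dominates and the nominal-rate
band check would measure that conservatism, not correctness (see the
methods note).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, hypergeom

from cnvdriver.association import fisher_exact_two_sided, region_scan
from cnvdriver.burden import gene_burden_scan
from cnvdriver.catalog import QdsgCatalog, QdsgEntry, build_catalog
from cnvdriver.models import CnvCall, GeneRecord, SampleTable
from cnvdriver.phenotypes import phenotype_scan
from cnvdriver.simulate import (
    CohortSpec,
    FamilySpec,
    case_carrier_freq,
    default_locus_grid,
    generate_cohort,
    generate_gene_annotation,
    generate_multiplex_families,
    generate_phenotypes,
    stream_rng,
)
from cnvdriver.tdt import binomial_tdt, count_transmissions


# ------------------------------------------------------------------ oracles

def enumeration_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration of the two-sided Fisher p-value."""
    row1, col1, total = a + b, a + c, a + b + c + d
    avals = np.arange(max(0, col1 - (total - row1)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(avals, total, col1, row1)
    p_obs = hypergeom.pmf(a, total, col1, row1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def fisher_enumeration_agreement(max_total: int = 40) -> tuple[float, int]:
    """Max |p - oracle| over ALL 2x2 tables with total <= max_total."""
    worst, n_tables = 0.0, 0
    for total in range(max_total + 1):
        for row1 in range(total + 1):
            row2 = total - row1
            for col1 in range(total + 1):
                amin, amax = max(0, col1 - row2), min(row1, col1)
                if amin > amax:
                    continue
                avals = np.arange(amin, amax + 1)
                pmf = hypergeom.pmf(avals, total, col1, row1)
                order = np.sort(pmf)
                cum = np.cumsum(order)
                idx = np.searchsorted(order, pmf * (1 + 1e-7), side="right")
                oracle = np.minimum(cum[idx - 1], 1.0)
                for a, p_expect in zip(avals, oracle):
                    b = row1 - a
                    c = col1 - a
                    d = row2 - c
                    p, _ = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
                    worst = max(worst, abs(p - p_expect))
                    n_tables += 1
    return worst, n_tables


def binomial_tail_agreement(max_n: int = 60) -> tuple[float, int]:
    """Max |p - direct tail sum| of the one-sided TDT test for all n <= max_n."""
    from cnvdriver.tdt import TransmissionCounts

    worst, n_checked = 0.0, 0
    for n in range(1, max_n + 1):
        tails = binom.pmf(np.arange(n + 1), n, 0.5)[::-1].cumsum()[::-1]
        for k in range(n + 1):
            p = binomial_tdt(TransmissionCounts(k, n)).p_value
            worst = max(worst, abs(p - float(tails[k])))
            n_checked += 1
    return worst, n_checked


# -------------------------------------------------------------- calibration

def null_region_scan_calibration(
    seed: int,
    n_cohorts: int = 10,
    n_loci: int = 200,
    n_per_arm: int = 2000,
    carrier_freq: float = 0.1,
) -> tuple[int, int]:
    """Per-locus tests with p < 0.05 on all-null cohorts: (hits, tests).

    Every locus has OR = 1, so the two-sided p should be uniform up to the
    discreteness of the exact test; polymorphic carrier frequencies keep
    that discreteness small.
    """
    loci = default_locus_grid(n_loci)
    hits = tests = 0
    for i in range(n_cohorts):
        spec = CohortSpec(
            n_cases=n_per_arm,
            n_controls=n_per_arm,
            loci=loci,
            risk_effects={l.locus_id: (carrier_freq, 1.0) for l in loci},
            background_cnv_rate=0.0,
            seed=seed + i,
        )
        calls, samples = generate_cohort(spec)
        scan = region_scan(calls, loci, samples)
        hits += sum(1 for r in scan.pooled if r.p_value < 0.05)
        tests += len(scan.pooled)
    return hits, tests


def binomial_99_band(n: int, p: float = 0.05) -> tuple[float, float]:
    """Exact central 99% band for a Binomial(n, p) fraction."""
    return float(binom.ppf(0.005, n, p) / n), float(binom.ppf(0.995, n, p) / n)


def null_tdt_calibration(seed: int, n_replicates: int = 300, n_families: int = 80) -> tuple[int, int]:
    """One-sided TDT false-positive count at Mendelian transmission: (hits, reps)."""
    genes = generate_gene_annotation(30, default_locus_grid(4), 1.0, 0.0, 0.0, seed=seed)
    ids = [g.gene_id for g in genes]
    hits = 0
    for i in range(n_replicates):
        spec = FamilySpec(
            n_families=n_families, transmission_prob=0.5, carrier_parent_freq=0.5,
            seed=seed + 1000 + i,
        )
        ped, calls = generate_multiplex_families(spec, genes)
        counts = count_transmissions(ped, calls, ids, genes)
        if counts.opportunities and binomial_tdt(counts).p_value < 0.05:
            hits += 1
    return hits, n_replicates


def null_phenotype_calibration(
    seed: int, n_replicates: int = 40, n_patients: int = 600, n_terms: int = 12
) -> tuple[int, int]:
    """Replicates with zero Bonferroni-significant pairs under the null: (clean, reps)."""
    patients = [f"p{i}" for i in range(n_patients)]
    background = {f"HP:{t:07d}": 0.08 for t in range(1, n_terms + 1)}
    clean = 0
    for i in range(n_replicates):
        rng = stream_rng(seed + i, "null_phenotypes.carriers")
        carriers = {
            f"G{g}": [patients[j] for j in rng.choice(n_patients, size=60, replace=False)]
            for g in range(8)
        }
        tab = generate_phenotypes(carriers, patients, {}, background, seed=seed + i)
        results = phenotype_scan(carriers, tab)
        if not any(r.significant for r in results):
            clean += 1
    return clean, n_replicates


# -------------------------------------------------------------------- power

def planted_locus_power(
    seed: int,
    n_replicates: int = 200,
    n_per_arm: int = 5000,
    n_loci: int = 10,
    carrier_freq: float = 0.01,
    odds_ratio: float = 10.0,
) -> tuple[int, int]:
    """Replicates where the planted locus is the Bonferroni-significant top hit."""
    loci = default_locus_grid(n_loci)
    planted = loci[0].locus_id
    hits = 0
    for i in range(n_replicates):
        effects = {l.locus_id: (carrier_freq, 1.0) for l in loci}
        effects[planted] = (carrier_freq, odds_ratio)
        spec = CohortSpec(
            n_cases=n_per_arm, n_controls=n_per_arm, loci=loci,
            risk_effects=effects, background_cnv_rate=0.0, seed=seed + i,
        )
        calls, samples = generate_cohort(spec)
        scan = region_scan(calls, loci, samples)
        res = {r.unit_id: r for r in scan.pooled}
        if res[planted].significant:
            hits += 1
    return hits, n_replicates


def tdt_power(
    seed: int,
    n_replicates: int = 500,
    transmission_prob: float = 0.75,
    min_opportunities: int = 100,
) -> tuple[int, int, float]:
    """Replicates with one-sided p < 0.05 at the planted over-transmission rate.

    Families are generated in batches until each replicate reaches the
    requested number of informative transmission opportunities. Returns
    (hits, replicates, mean transmission estimate).
    """
    genes = generate_gene_annotation(30, default_locus_grid(4), 1.0, 0.0, 0.0, seed=seed)
    ids = [g.gene_id for g in genes]
    hits, estimates = 0, []
    for i in range(n_replicates):
        k = n = 0
        batch = 0
        while n < min_opportunities:
            spec = FamilySpec(
                n_families=24, transmission_prob=transmission_prob,
                carrier_parent_freq=0.5, seed=seed + 7919 * i + batch,
            )
            ped, calls = generate_multiplex_families(spec, genes)
            counts = count_transmissions(ped, calls, ids, genes)
            k += counts.transmitted
            n += counts.opportunities
            batch += 1
        from cnvdriver.tdt import TransmissionCounts

        res = binomial_tdt(TransmissionCounts(k, n))
        estimates.append(res.estimate)
        if res.p_value < 0.05:
            hits += 1
    return hits, n_replicates, float(np.mean(estimates))


def burden_power(
    seed: int,
    n_replicates: int = 200,
    n_cases: int = 4000,
    n_controls: int = 2500,
    n_genes: int = 10,
    carrier_freq: float = 0.01,
    odds_ratio: float = 8.0,
) -> tuple[int, int]:
    """Replicates where the planted case-excess gene passes its tier threshold."""
    regions = default_locus_grid(2)
    genes = generate_gene_annotation(n_genes, regions, 1.0, 0.0, 0.0, seed=seed)
    catalog = build_catalog(genes, regions)
    planted = genes[0]
    f_case = case_carrier_freq(carrier_freq, odds_ratio)
    status = {f"case{i}": "case" for i in range(n_cases)}
    status.update({f"ctrl{i}": "control" for i in range(n_controls)})
    samples = SampleTable(status)
    hits = 0
    for i in range(n_replicates):
        rng = stream_rng(seed + i, "burden_power")
        case_del, ctrl_del = [], []
        for g in genes:
            fc = f_case if g.gene_id == planted.gene_id else carrier_freq
            for s in np.flatnonzero(rng.random(n_cases) < fc):
                case_del.append(CnvCall(g.chrom, g.cds_start, g.cds_end, "DEL", f"case{s}"))
            for s in np.flatnonzero(rng.random(n_controls) < carrier_freq):
                ctrl_del.append(CnvCall(g.chrom, g.cds_start, g.cds_end, "DEL", f"ctrl{s}"))
        results = {r.unit_id: r for r in gene_burden_scan(
            catalog, case_del, [], ctrl_del, genes, samples)}
        if results[planted.gene_id].significant:
            hits += 1
    return hits, n_replicates


# --------------------------------------------------------------- structure

def top5_recovery(seed: int, n_genes: int = 200, n_strata: int = 12) -> float:
    """Worst per-stratum recovery of the planted top-5% expression set."""
    from cnvdriver.expression import STAGES, top_percentile_flags, variance_stabilize
    from cnvdriver.simulate import generate_expression

    regions = ["neocortex", "amygdala"]
    strata = [(s, r) for s in STAGES for r in regions][:n_strata]
    planted = [f"G{i + 1:05d}" for i in range(int(0.05 * n_genes))]
    em = generate_expression(n_genes, strata, planted, seed=seed)
    flags = top_percentile_flags(variance_stabilize(em.counts), em.sample_meta)
    worst = 1.0
    for col in flags.columns:
        flagged = set(flags.index[flags[col]])
        worst = min(worst, len(flagged & set(planted)) / len(planted))
    return worst


def tier_recovery_exact(seed: int) -> bool:
    """Does tiering recover the generator-planted HI/TS/bHITS counts exactly?"""
    regions = default_locus_grid(5)
    genes = generate_gene_annotation(200, regions, 0.12, 0.03, 0.05, seed=seed)
    cat = build_catalog(genes, regions)
    return cat.tier_counts == {"HI": 24, "TS": 6, "bHITS": 10}
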