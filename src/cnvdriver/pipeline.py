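"""End-to-end orchestration of the pipeline stages from a single YAML config.

Stage order: simulate -> region_scan -> catalog -> enrichment -> tdt ->
burden -> expression -> phenotypes -> network. Every stage writes TSVs
under the output directory and registers them in a manifest
(manifest.json: config, seeds, package version, SHA-256 per output), so
re-running an identical config reproduces identical files. All analysis
thresholds (tier cutoffs 0.84 / 0.993, AF 0.001, common-overlap 0.5,
alpha 0.05, expression percentile 0.95, interaction score 0.4) live in
the config with those values as defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

import cnvdriver
from cnvdriver import io as cio
from cnvdriver.association import classify_novelty, region_scan
from cnvdriver.burden import RarityConfig, filter_rare, gene_burden_scan
from cnvdriver.catalog import build_catalog
from cnvdriver.enrichment import catalog_enrichment
from cnvdriver.expression import (
    expression_enrichment,
    persistent_high_expression,
    top_percentile_flags,
    variance_stabilize,
)
from cnvdriver.models import Locus
from cnvdriver.network import (
    InteractionNetwork,
    connectivity_stats,
    edge_enrichment,
    filter_edges,
    intra_region_connectivity,
)
from cnvdriver.phenotypes import phenotype_scan
from cnvdriver.simulate import (
    CohortSpec,
    FamilySpec,
    default_locus_grid,
    generate_cohort,
    generate_expression,
    generate_gene_annotation,
    generate_multiplex_families,
    generate_phenotypes,
    stream_rng,
)
from cnvdriver.tdt import binomial_tdt, count_transmissions

STAGES = (
    "simulate",
    "region_scan",
    "catalog",
    "enrichment",
    "tdt",
    "burden",
    "expression",
    "phenotypes",
    "network",
)

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "alpha": 0.05,
    "phi_cutoff": 0.84,
    "pts_cutoff": 0.993,
    "af_threshold": 0.001,
    "max_common_overlap": 0.5,
    "expression_percentile": 0.95,
    "min_interaction_score": 0.4,
    "novelty_overlap_frac": 0.5,
    "cohort": {
        "n_cases": 2000,
        "n_controls": 2000,
        "n_loci": 40,
        "n_risk_loci": 4,
        "carrier_freq_controls": 0.01,
        "odds_ratio": 10.0,
        "background_cnv_rate": 0.5,
    },
    "annotation": {"n_genes": 400, "hi_frac": 0.10, "ts_frac": 0.02, "bhits_frac": 0.02},
    "families": {
        "n_families": 493,
        "n_affected_children_range": [2, 3],
        "transmission_prob": 0.726,
        "carrier_parent_freq": 0.15,
    },
    "expression": {
        "strata_regions": ["neocortex", "amygdala", "cerebellum"],
        "nb_mean": 50.0,
        "nb_dispersion": 0.3,
        "samples_per_stratum": 4,
    },
    "phenotypes": {"n_patients": 1500, "background_incidence": 0.05, "effect_incidence": 0.6},
    "network": {"n_permutations": 500, "edge_prob": 0.02, "clique_edge_prob": 0.35},
}


def _merge(base: Mapping[str, Any], over: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> Path:
    """Run the requested stages and return the output directory.

    ``config`` is a YAML path or an equivalent mapping; unknown stage names
    and stages whose upstream outputs were not requested are errors.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user_cfg = yaml.safe_load(fh) or {}
    else:
        user_cfg = dict(config)
    cfg = _merge(DEFAULTS, user_cfg)
    stages = list(cfg.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}; valid: {list(STAGES)}")
    needs_sim = [s for s in stages if s != "simulate"]
    if needs_sim and "simulate" not in stages:
        raise PipelineError(f"stage(s) {needs_sim} need the 'simulate' stage upstream")

    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "results/pipeline"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    alpha = float(cfg["alpha"])
    manifest: dict[str, Any] = {
        "package": "cnvdriver",
        "version": cnvdriver.__version__,
        "seed": seed,
        "config": cfg,
        "outputs": {},
    }

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path.name), "sha256": _sha256(path)}

    state: dict[str, Any] = {}

    if "simulate" in stages:
        ccfg = cfg["cohort"]
        loci = default_locus_grid(int(ccfg["n_loci"]))
        risk = {
            loci[i].locus_id: (float(ccfg["carrier_freq_controls"]), float(ccfg["odds_ratio"]))
            for i in range(int(ccfg["n_risk_loci"]))
        }
        spec = CohortSpec(
            n_cases=int(ccfg["n_cases"]),
            n_controls=int(ccfg["n_controls"]),
            loci=loci,
            risk_effects=risk,
            background_cnv_rate=float(ccfg["background_cnv_rate"]),
            seed=seed,
        )
        calls, samples = generate_cohort(spec)
        acfg = cfg["annotation"]
        genes = generate_gene_annotation(
            int(acfg["n_genes"]), loci[: max(len(risk), 1)],
            float(acfg["hi_frac"]), float(acfg["ts_frac"]), float(acfg["bhits_frac"]),
            seed=seed,
        )
        state.update(loci=loci, risk=risk, calls=calls, samples=samples, genes=genes)
        cio.write_cnv_bed(calls, out / "cnv_calls.bed.tsv")
        cio.write_samples(samples, out / "samples.tsv")
        cio.write_loci(loci, out / "loci.tsv")
        cio.write_gene_table(genes, out / "genes.tsv")
        for name in ("cnv_calls.bed.tsv", "samples.tsv", "loci.tsv", "genes.tsv"):
            register(name, out / name)

    if "region_scan" in stages:
        scan = region_scan(state["calls"], state["loci"], state["samples"], alpha=alpha)
        state["scan"] = scan
        sig_ids = {r.unit_id for r in scan.significant}
        state["sig_loci"] = [l for l in state["loci"] if l.locus_id in sig_ids]
        cio.write_results(scan.pooled, out / "region_scan.tsv")
        register("region_scan.tsv", out / "region_scan.tsv")
        reference = [
            Locus(f"ref_{l.locus_id}", l.chrom, l.start, l.end) for l in state["loci"][:2]
        ]
        calls = classify_novelty(state["sig_loci"], reference, float(cfg["novelty_overlap_frac"]))
        with open(out / "novelty.tsv", "w") as fh:
            fh.write("locus_id\tstatus\tmatched_reference_ids\n")
            for nc in calls:
                fh.write(f"{nc.locus_id}\t{nc.status}\t{','.join(nc.matched_reference_ids) or '.'}\n")
        register("novelty.tsv", out / "novelty.tsv")

    if "catalog" in stages:
        cat = build_catalog(
            state["genes"], state["sig_loci"],
            float(cfg["phi_cutoff"]), float(cfg["pts_cutoff"]),
        )
        state["catalog"] = cat
        with open(out / "qdsg_catalog.tsv", "w") as fh:
            fh.write("gene_id\tregion_id\ttier\n")
            for e in cat.entries:
                fh.write(f"{e.gene_id}\t{e.region_id}\t{e.tier}\n")
        register("qdsg_catalog.tsv", out / "qdsg_catalog.tsv")

    if "enrichment" in stages:
        cat = state["catalog"]
        universe = [g.gene_id for g in state["genes"]]
        rng = stream_rng(seed, "pipeline.reference_sets")
        qdsg = cat.genes()
        known = list(qdsg[: len(qdsg) // 2]) + [
            universe[i] for i in rng.choice(len(universe), size=30, replace=False)
        ]
        sets = {"known_risk_genes": sorted(set(known))}
        results = catalog_enrichment(qdsg, sets, universe, alpha=alpha) if qdsg else []
        cio.write_results(results, out / "enrichment.tsv")
        register("enrichment.tsv", out / "enrichment.tsv")

    if "tdt" in stages:
        fcfg = cfg["families"]
        hi_genes = state["catalog"].genes("HI") or [g.gene_id for g in state["genes"][:5]]
        gene_by_id = {g.gene_id: g for g in state["genes"]}
        fam_spec = FamilySpec(
            n_families=int(fcfg["n_families"]),
            n_affected_children_range=tuple(fcfg["n_affected_children_range"]),
            transmission_prob=float(fcfg["transmission_prob"]),
            carrier_parent_freq=float(fcfg["carrier_parent_freq"]),
            seed=seed,
        )
        ped, fam_calls = generate_multiplex_families(
            fam_spec, [gene_by_id[g] for g in hi_genes]
        )
        cio.write_ped(ped, out / "families.ped")
        cio.write_cnv_bed(fam_calls, out / "family_deletions.bed.tsv")
        rows = []
        for origin in ("maternal", "paternal", "combined"):
            counts = count_transmissions(ped, fam_calls, hi_genes, state["genes"], origin)
            res = binomial_tdt(counts)
            rows.append(res)
        with open(out / "tdt.tsv", "w") as fh:
            fh.write("origin\ttransmitted\topportunities\testimate\tci_low\tci_high\tp_value\n")
            for r in rows:
                fh.write(
                    f"{r.parent_of_origin}\t{r.transmitted}\t{r.opportunities}"
                    f"\t{r.estimate!r}\t{r.ci_low!r}\t{r.ci_high!r}\t{r.p_value!r}\n"
                )
        for name in ("families.ped", "family_deletions.bed.tsv", "tdt.tsv"):
            register(name, out / name)

    if "burden" in stages:
        rng = stream_rng(seed, "pipeline.common_variants")
        common = []
        for i, locus in enumerate(state["loci"][-3:]):
            common.append(
                type(state["calls"][0])(
                    locus.chrom, locus.start, locus.end,
                    "DEL" if i % 2 == 0 else "DUP", f"common{i}", float(rng.uniform(0.001, 0.2)),
                )
            )
        rarity = RarityConfig(float(cfg["af_threshold"]), float(cfg["max_common_overlap"]))
        case_ids = set(state["samples"].case_ids)
        rare = filter_rare(state["calls"], common, rarity)
        case_del = [c for c in rare if c.sample_id in case_ids and c.cnv_type == "DEL"]
        case_dup = [c for c in rare if c.sample_id in case_ids and c.cnv_type == "DUP"]
        ctrl = [c for c in rare if c.sample_id not in case_ids]
        results = gene_burden_scan(
            state["catalog"], case_del, case_dup, ctrl, state["genes"], state["samples"],
            alpha=alpha,
        )
        cio.write_results(results, out / "gene_burden.tsv")
        register("gene_burden.tsv", out / "gene_burden.tsv")

    if "expression" in stages:
        ecfg = cfg["expression"]
        from cnvdriver.expression import STAGES as DEV_STAGES

        strata = [(s, r) for s in DEV_STAGES for r in ecfg["strata_regions"]]
        n_genes = len(state["genes"])
        planted = state["catalog"].genes()[: max(1, int(0.05 * n_genes))]
        em = generate_expression(
            n_genes, strata, planted,
            nb_mean=float(ecfg["nb_mean"]), nb_dispersion=float(ecfg["nb_dispersion"]),
            seed=seed, samples_per_stratum=int(ecfg["samples_per_stratum"]),
        )
        cio.write_expression(em, out / "expression_counts.tsv", out / "expression_samples.tsv")
        vst = variance_stabilize(em.counts)
        flags = top_percentile_flags(vst, em.sample_meta, q=float(cfg["expression_percentile"]))
        enr = expression_enrichment(state["catalog"], flags, alpha=alpha)
        cio.write_results(enr, out / "expression_enrichment.tsv")
        persistent = persistent_high_expression(flags)
        (out / "persistent_high_expression.txt").write_text("\n".join(persistent) + "\n")
        for name in (
            "expression_counts.tsv", "expression_samples.tsv",
            "expression_enrichment.tsv", "persistent_high_expression.txt",
        ):
            register(name, out / name)

    if "phenotypes" in stages:
        pcfg = cfg["phenotypes"]
        patients = [f"pat{i + 1:05d}" for i in range(int(pcfg["n_patients"]))]
        qdsg = state["catalog"].genes()
        rng = stream_rng(seed, "pipeline.carriers")
        gene_carriers = {
            g: [patients[j] for j in rng.choice(len(patients), size=60, replace=False)]
            for g in qdsg[:10]
        }
        background = {f"HP:{i:07d}": float(pcfg["background_incidence"]) for i in range(1, 21)}
        effects = {
            (g, f"HP:{i + 1:07d}"): float(pcfg["effect_incidence"])
            for i, g in enumerate(list(gene_carriers)[:3])
        }
        table = generate_phenotypes(gene_carriers, patients, effects, background, seed=seed)
        cio.write_phenotypes(table, out / "phenotypes.tsv")
        results = phenotype_scan(gene_carriers, table, alpha=alpha)
        cio.write_results(results, out / "phenotype_scan.tsv")
        for name in ("phenotypes.tsv", "phenotype_scan.tsv"):
            register(name, out / name)

    if "network" in stages:
        ncfg = cfg["network"]
        universe = [g.gene_id for g in state["genes"]]
        qdsg = state["catalog"].genes()
        rng = stream_rng(seed, "pipeline.network")
        edges: dict[tuple[str, str], float] = {}
        n = len(universe)
        n_bg = rng.binomial(n * (n - 1) // 2, float(ncfg["edge_prob"]))
        while len(edges) < n_bg:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            key = tuple(sorted((universe[i], universe[j])))
            edges.setdefault(key, float(rng.uniform(0.15, 1.0)))
        for i, g1 in enumerate(qdsg):
            for g2 in qdsg[i + 1:]:
                if rng.random() < float(ncfg["clique_edge_prob"]):
                    edges[tuple(sorted((g1, g2)))] = float(rng.uniform(0.4, 1.0))
        net = InteractionNetwork(
            [(a, b, s) for (a, b), s in sorted(edges.items())], nodes=universe
        )
        cio.write_edge_list(net.edges, out / "interactions.tsv")
        high_conf = filter_edges(net, float(cfg["min_interaction_score"]))
        stats = connectivity_stats(high_conf, qdsg)
        expected, p = edge_enrichment(
            high_conf, qdsg, n_permutations=int(ncfg["n_permutations"]),
            seed=seed,
        )
        region_genes: dict[str, list[str]] = {}
        for e in state["catalog"].entries:
            region_genes.setdefault(e.region_id, []).append(e.gene_id)
        intra = intra_region_connectivity(region_genes, high_conf)
        with open(out / "network_stats.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"observed_edges\t{stats.observed_edges}\n")
            fh.write(f"expected_edges\t{expected!r}\n")
            fh.write(f"permutation_p\t{p!r}\n")
            fh.write(f"avg_node_degree\t{stats.avg_node_degree!r}\n")
            fh.write(f"avg_clustering_coeff\t{stats.avg_clustering_coeff!r}\n")
            fh.write(f"transitivity\t{stats.transitivity!r}\n")
            for region, (d1, d2) in sorted(intra.items()):
                fh.write(f"intra_region_pairs_d1[{region}]\t{d1}\n")
                fh.write(f"intra_region_pairs_d2[{region}]\t{d2}\n")
        for name in ("interactions.tsv", "network_stats.tsv"):
            register(name, out / name)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
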