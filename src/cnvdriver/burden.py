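"""Rare-CNV filtering and per-gene case-control burden testing.

Rarity follows the common-variant masking rule: a CNV is rare when it is
not covered more than 50% by the union of common variants (allele
frequency >= 0.001) of the same type. The per-gene test compares rare-CNV
carrier frequencies between cases and controls, with the CNV class matched
to the gene's dosage tier (deletions for HI genes, duplications for TS
genes, both pooled for bHITS) and a tier-specific Bonferroni threshold
alpha / tier size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from cnvdriver.association import bonferroni_threshold, fisher_exact_two_sided
from cnvdriver.catalog import QdsgCatalog
from cnvdriver.intervals import fraction_covered, merge_spans
from cnvdriver.models import AssociationResult, CnvCall, GeneRecord, SampleTable

TIER_CLASSES = {"HI": ("DEL",), "TS": ("DUP",), "bHITS": ("DEL", "DUP")}


@dataclass(frozen=True)
class RarityConfig:
    """Thresholds of the common-variant masking rule."""

    af_threshold: float = 0.001
    max_common_overlap: float = 0.5

    def __post_init__(self) -> None:
        for name, v in (("af_threshold", self.af_threshold),
                        ("max_common_overlap", self.max_common_overlap)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def filter_rare(
    cnvs: Sequence[CnvCall],
    common_variants: Sequence[CnvCall],
    config: RarityConfig = RarityConfig(),
) -> list[CnvCall]:
    """Drop CNVs covered more than ``max_common_overlap`` by common variants.

    Coverage is the fraction of the QUERY covered by the union of common
    variants of the same type with AF >= af_threshold; exactly 50% coverage
    is not "more than 50%", so such a CNV is retained. Masking is
    type-matched (DEL against common DELs, DUP against common DUPs).
    """
    for cv in common_variants:
        if cv.af is None:
            raise ValueError(
                f"common variant {cv.chrom}:{cv.start}-{cv.end} lacks an allele frequency"
            )
    # pre-merge the common-variant union per (chrom, type) once
    masks: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for cv in common_variants:
        if cv.af >= config.af_threshold:
            masks.setdefault((cv.chrom, cv.cnv_type), []).append((cv.start, cv.end))
    merged = {key: merge_spans(spans) for key, spans in masks.items()}

    kept: list[CnvCall] = []
    for cnv in cnvs:
        spans = merged.get((cnv.chrom, cnv.cnv_type), [])
        covered = sum(max(0, min(e, cnv.end) - max(s, cnv.start)) for s, e in spans)
        if covered / cnv.length <= config.max_common_overlap:
            kept.append(cnv)
    return kept


def _carriers(
    cnvs: Sequence[CnvCall], gene: GeneRecord, containment: bool
) -> set[str]:
    out: set[str] = set()
    for c in cnvs:
        if c.chrom != gene.chrom:
            continue
        if containment:
            hit = c.start <= gene.cds_start and gene.cds_end <= c.end
        else:
            hit = min(c.end, gene.cds_end) - max(c.start, gene.cds_start) > 0
        if hit:
            out.add(c.sample_id)
    return out


def gene_burden_scan(
    catalog: QdsgCatalog,
    case_cnvs_del: Sequence[CnvCall],
    case_cnvs_dup: Sequence[CnvCall],
    control_cnvs: Sequence[CnvCall],
    gene_table: Sequence[GeneRecord],
    samples: SampleTable,
    alpha: float = 0.05,
    containment: bool = False,
) -> list[AssociationResult]:
    """Per-gene carrier-frequency comparison between cases and controls.

    Inputs are expected to be pre-filtered to rare CNVs. "Hitting the gene"
    means >= 1 bp of overlap with the CDS span (``containment=True``
    switches to requiring the CNV to span the whole CDS). For each gene the
    primary result (unit_id = gene ID) uses the tier-matched CNV class;
    per-class results (unit_id = "gene|DEL" etc.) are emitted as well, all
    at the tier's threshold alpha / tier size.
    """
    if samples.n_cases == 0 or samples.n_controls == 0:
        raise ValueError("gene_burden_scan needs at least one case and one control")
    genes_by_id = {g.gene_id: g for g in gene_table}
    tier_counts = catalog.tier_counts

    ctrl_by_type = {
        t: [c for c in control_cnvs if c.cnv_type == t] for t in ("DEL", "DUP")
    }
    case_by_type = {
        "DEL": [c for c in case_cnvs_del if c.cnv_type == "DEL"],
        "DUP": [c for c in case_cnvs_dup if c.cnv_type == "DUP"],
    }

    results: list[AssociationResult] = []
    for gene_id in catalog.genes():
        tier = catalog.tier_of(gene_id)
        gene = genes_by_id.get(gene_id)
        if gene is None:
            raise ValueError(f"catalog gene {gene_id!r} missing from gene table")
        threshold = bonferroni_threshold(alpha, tier_counts[tier])
        classes = TIER_CLASSES[tier]

        per_class: dict[str, tuple[set[str], set[str]]] = {}
        for t in ("DEL", "DUP"):
            per_class[t] = (
                _carriers(case_by_type[t], gene, containment),
                _carriers(ctrl_by_type[t], gene, containment),
            )

        case_carr = set().union(*(per_class[t][0] for t in classes))
        ctrl_carr = set().union(*(per_class[t][1] for t in classes))
        results.append(_burden_result(gene_id, case_carr, ctrl_carr, samples, threshold))
        for t in ("DEL", "DUP"):
            results.append(
                _burden_result(
                    f"{gene_id}|{t}", per_class[t][0], per_class[t][1], samples, threshold
                )
            )
    return results


def _burden_result(
    unit_id: str,
    case_carriers: set[str],
    control_carriers: set[str],
    samples: SampleTable,
    threshold: float,
) -> AssociationResult:
    a = sum(1 for s in samples.case_ids if s in case_carriers)
    c = sum(1 for s in samples.control_ids if s in control_carriers)
    b = samples.n_cases - a
    d = samples.n_controls - c
    p, orat = fisher_exact_two_sided(a, b, c, d)
    or_gt_1 = (not math.isnan(orat)) and orat > 1.0
    return AssociationResult(
        unit_id=unit_id,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=orat,
        p_value=p,
        bonferroni_threshold=threshold,
        significant=bool(p < threshold and or_gt_1),
        nominal=bool(p < 0.05 and or_gt_1),
    )
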