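"""Developmental brain-expression analysis.

Counts are normalized with median-of-ratios size factors and a log2
transform, genes are ranked within each (developmental stage, brain
region) stratum, the top 5% are flagged, and the flagged sets are tested
for qDSG over-representation. Because top-5% membership is rank-based
within each stratum, any monotone variance-stabilizing map of the
normalized counts yields identical flags; the log2(x+1) transform is used
as that map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cnvdriver.catalog import TIERS, QdsgCatalog
from cnvdriver.enrichment import gene_set_enrichment
from cnvdriver.models import AssociationResult

STAGES = ("fetal", "perinatal", "infancy", "childhood", "adolescence", "adulthood")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) plus per-sample stage and brain-region labels."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame  # index: sample, columns: stage, brain_region

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("expression counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without stage/region labels, e.g. {missing[:5]}")
        for col in ("stage", "brain_region"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    @property
    def strata(self) -> list[tuple[str, str]]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return sorted(set(zip(meta["stage"], meta["brain_region"])))

    def samples_in(self, stage: str, brain_region: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        mask = (meta["stage"] == stage) & (meta["brain_region"] == brain_region)
        return list(meta.index[mask])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    Genes observed in every sample define the pseudo-reference (geometric
    mean per gene); each sample's factor is the median ratio of its counts
    to that reference.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = list(counts.columns[counts.sum(axis=0) == 0])
        raise ValueError(f"sample(s) with all-zero counts: {bad[:5]}")
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has nonzero counts in every sample; size factors undefined")
    log_ref = np.log(positive).mean(axis=1)
    sf = np.exp(np.median(np.log(positive).sub(log_ref, axis=0), axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def variance_stabilize(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-normalized log2(x + 1) transform of a count matrix."""
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


def top_percentile_flags(
    transformed: pd.DataFrame,
    sample_meta: pd.DataFrame,
    q: float = 0.95,
    summary: str = "mean",
) -> pd.DataFrame:
    """Flag genes at or above the q-th percentile of per-stratum expression.

    Genes are summarized per stratum (mean of transformed values over the
    stratum's samples; ``summary="median"`` available) and flagged when the
    summary reaches the empirical q-th percentile. Ties at the threshold
    are all included, so the flag count is ceil((1-q)*G) plus ties — with
    every gene identical, all genes tie at the threshold and all are
    flagged. Returns a boolean genes x strata frame with (stage, region)
    column MultiIndex.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    em = ExpressionMatrix(transformed, sample_meta)  # reuses the label validation
    flags = {}
    for stage, region in em.strata:
        cols = em.samples_in(stage, region)
        stat = transformed[cols].mean(axis=1) if summary == "mean" else transformed[cols].median(axis=1)
        thr = np.quantile(stat.values, q, method="higher")
        flags[(stage, region)] = stat >= thr
    out = pd.DataFrame(flags)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stage", "brain_region"])
    return out


def expression_enrichment(
    catalog: QdsgCatalog,
    flags: pd.DataFrame,
    universe: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """qDSG over-representation among top-expressed genes, per stratum x tier.

    The universe defaults to all genes in the flag matrix; tier gene sets
    are intersected with it. Bonferroni correction is over the number of
    (stratum, tier) tests performed.
    """
    uni = list(flags.index) if universe is None else list(universe)
    uni_set = set(uni)
    tests: list[tuple[str, list[str], list[str]]] = []
    for stage, region in flags.columns:
        flagged = list(flags.index[flags[(stage, region)]])
        for tier in TIERS:
            tier_genes = [g for g in catalog.genes(tier) if g in uni_set]
            if not tier_genes:
                continue
            tests.append((f"{stage}|{region}|{tier}", tier_genes, flagged))
    return [
        gene_set_enrichment(tg, fl, uni, unit_id=uid, alpha=alpha, n_tests=max(len(tests), 1))
        for uid, tg, fl in tests
    ]


def persistent_high_expression(
    flags: pd.DataFrame,
    stages: Sequence[str] = STAGES,
    all_regions: bool = False,
) -> list[str]:
    """Genes staying in the top percentile across every developmental stage.

    Default: the gene must be flagged at every stage within at least one
    brain region (``all_regions=True`` requires every region). Only stages
    present in the flag matrix are required; regions are those assayed at
    every required stage.
    """
    present_stages = [s for s in stages if s in flags.columns.get_level_values("stage")]
    if not present_stages:
        raise ValueError("flag matrix contains none of the requested stages")
    regions = set(flags.columns.get_level_values("brain_region"))
    regions = [
        r for r in sorted(regions)
        if all((s, r) in flags.columns for s in present_stages)
    ]
    if not regions:
        raise ValueError("no brain region is assayed at every developmental stage")
    per_region = {
        r: flags[[(s, r) for s in present_stages]].all(axis=1) for r in regions
    }
    combined = pd.DataFrame(per_region)
    keep = combined.all(axis=1) if all_regions else combined.any(axis=1)
    return list(flags.index[keep])
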