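"""Transmission-disequilibrium testing of rare deletions in multiplex families.

Deletions hitting haploinsufficient risk genes should, under Mendelian
segregation, reach each child with probability 1/2; over-transmission to
affected children is evidence that the gene contributes to the phenotype.
The counting unit is the (carrier parent, affected child) pair per
gene-level deletion — every affected sibling contributes one opportunity
per carrier parent — with a per-family collapsed mode available since the
family-level convention is also in use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import binomtest

from cnvdriver.intervals import overlap_bp
from cnvdriver.models import AFFECTED, PED_MISSING, CnvCall, GeneRecord, Pedigree

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"
COMBINED = "combined"


@dataclass(frozen=True)
class TransmissionCounts:
    transmitted: int
    opportunities: int
    parent_of_origin: str = COMBINED

    def __post_init__(self) -> None:
        if not (0 <= self.transmitted <= self.opportunities):
            raise ValueError("need 0 <= transmitted <= opportunities")
        if self.parent_of_origin not in (MATERNAL, PATERNAL, COMBINED):
            raise ValueError(f"bad parent_of_origin {self.parent_of_origin!r}")


@dataclass(frozen=True)
class TdtResult:
    """One-sided exact binomial test of over-transmission.

    p = P(X >= k | n, null_rate); the CI is the two-sided 95%
    Clopper-Pearson interval for the transmission probability.
    """

    p_value: float
    estimate: float
    ci_low: float
    ci_high: float
    transmitted: int
    opportunities: int
    parent_of_origin: str = COMBINED

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _gene_hits(
    cnv_by_sample: Mapping[str, list[CnvCall]],
    sample_id: str,
    genes: Sequence[GeneRecord],
) -> set[str]:
    hits: set[str] = set()
    for cnv in cnv_by_sample.get(sample_id, []):
        for g in genes:
            if overlap_bp(cnv, _Span(g.chrom, g.cds_start, g.cds_end)) > 0:
                hits.add(g.gene_id)
    return hits


@dataclass(frozen=True)
class _Span:
    chrom: str
    start: int
    end: int


def count_transmissions(
    pedigree: Pedigree,
    deletions: Sequence[CnvCall],
    hi_genes: Sequence[str],
    gene_table: Sequence[GeneRecord],
    parent_of_origin: str = COMBINED,
    per_family: bool = False,
) -> TransmissionCounts:
    """Count parent-to-affected-child transmissions of gene-level deletions.

    A parent is informative for a gene when it carries a deletion
    overlapping that gene's CDS; each affected child of that parent is one
    opportunity, and a transmission is recorded when the child also carries
    a deletion overlapping the same gene (boundary identity is not required
    — array-era calls have imprecise breakpoints). A child deletion seen in
    neither parent is de novo, not a transmission, and is logged and
    ignored. When BOTH parents carry a deletion hitting the same gene, the
    child's carrier status cannot be attributed to either parent at gene
    level, so those opportunities are excluded as uninformative — the
    standard TDT treatment of double-carrier matings; counting them would
    inflate the apparent transmission rate under the Mendelian null. With
    ``per_family=True`` each (family, parent, gene) triple is
    collapsed to a single opportunity, transmitted if any affected child
    carries it.
    """
    if parent_of_origin not in (MATERNAL, PATERNAL, COMBINED):
        raise ValueError(f"bad parent_of_origin {parent_of_origin!r}")
    if not hi_genes:
        raise ValueError("hi_genes is empty")
    bad = [c.cnv_type for c in deletions if c.cnv_type != "DEL"]
    if bad:
        raise ValueError("count_transmissions expects deletions only")

    hi_set = set(hi_genes)
    genes = [g for g in gene_table if g.gene_id in hi_set]
    missing = hi_set - {g.gene_id for g in genes}
    if missing:
        raise ValueError(f"HI genes missing from gene table, e.g. {sorted(missing)[:5]}")

    cnv_by_sample: dict[str, list[CnvCall]] = {}
    for cnv in deletions:
        cnv_by_sample.setdefault(cnv.sample_id, []).append(cnv)

    k = n = 0
    for fid, members in pedigree.families().items():
        children = [m for m in members if m.affected == AFFECTED and
                    (m.father_id != PED_MISSING or m.mother_id != PED_MISSING)]
        if not children:
            continue
        parent_hits = {
            m.individual_id: _gene_hits(cnv_by_sample, m.individual_id, genes)
            for m in members
        }
        for child in children:
            child_hits = _gene_hits(cnv_by_sample, child.individual_id, genes)
            inherited_pool = parent_hits.get(child.father_id, set()) | parent_hits.get(
                child.mother_id, set()
            )
            for g in child_hits - inherited_pool:
                logger.warning(
                    "family %s: deletion of %s in child %s absent from both parents "
                    "(de novo) — excluded from transmission counting",
                    fid, g, child.individual_id,
                )
        origins = []
        if parent_of_origin in (MATERNAL, COMBINED):
            origins.append("mother")
        if parent_of_origin in (PATERNAL, COMBINED):
            origins.append("father")
        for which in origins:
            parent_of = {
                c.individual_id: (c.mother_id if which == "mother" else c.father_id)
                for c in children
            }
            other_of = {
                c.individual_id: (c.father_id if which == "mother" else c.mother_id)
                for c in children
            }
            triples: dict[tuple[str, str], tuple[int, int]] = {}
            for child in children:
                pid = parent_of[child.individual_id]
                if pid == PED_MISSING:
                    continue
                child_hits = _gene_hits(cnv_by_sample, child.individual_id, genes)
                other_hits = parent_hits.get(other_of[child.individual_id], set())
                for g in parent_hits.get(pid, set()):
                    if g in other_hits:
                        continue  # double-carrier mating: uninformative
                    kk, nn = triples.get((pid, g), (0, 0))
                    triples[(pid, g)] = (kk + (1 if g in child_hits else 0), nn + 1)
            for kk, nn in triples.values():
                if per_family:
                    k += 1 if kk > 0 else 0
                    n += 1
                else:
                    k += kk
                    n += nn
    return TransmissionCounts(k, n, parent_of_origin)


def binomial_tdt(counts: TransmissionCounts, null_rate: float = 0.5) -> TdtResult:
    """One-sided exact binomial test of over-transmission against null_rate."""
    if counts.opportunities < 1:
        raise ValueError("no transmission opportunities")
    k, n = counts.transmitted, counts.opportunities
    p = float(binomtest(k, n, null_rate, alternative="greater").pvalue)
    ci = binomtest(k, n, null_rate).proportion_ci(confidence_level=0.95, method="exact")
    return TdtResult(
        p_value=p,
        estimate=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        transmitted=k,
        opportunities=n,
        parent_of_origin=counts.parent_of_origin,
    )
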