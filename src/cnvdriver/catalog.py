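"""Dosage-sensitivity tiering and the qualifying dosage-sensitive gene catalog.

A qDSG is a gene whose CDS is fully contained in a significant risk region
and whose (pHI, pTS) scores pass the haploinsufficiency / triplosensitivity
cutoffs (pHI >= 0.84, pTS >= 0.993). The tier point (0.84, 0.993) itself
belongs to bHITS: both-score genes take priority, and HI/TS require the
opposing score to fall strictly below its cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from cnvdriver.intervals import fully_contains
from cnvdriver.models import GeneRecord, Locus

PHI_CUTOFF = 0.84
PTS_CUTOFF = 0.993

TIERS = ("HI", "TS", "bHITS")


def tier_dosage_sensitivity(
    phi: float,
    pts: float,
    phi_cutoff: float = PHI_CUTOFF,
    pts_cutoff: float = PTS_CUTOFF,
) -> str | None:
    """Tier a gene by its dosage-sensitivity scores; None when neither passes."""
    for name, score in (("pHI", phi), ("pTS", pts)):
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"{name} score {score} outside [0, 1]")
    hi = phi >= phi_cutoff
    ts = pts >= pts_cutoff
    if hi and ts:
        return "bHITS"
    if hi:
        return "HI"
    if ts:
        return "TS"
    return None


@dataclass
class QdsgEntry:
    gene_id: str
    region_id: str
    tier: str


@dataclass
class QdsgCatalog:
    """qDSG entries per (gene, region), with tier counts deduplicated by gene.

    A gene contained in two overlapping risk regions is listed once per
    region but counted once in ``tier_counts``.
    """

    entries: list[QdsgEntry] = field(default_factory=list)

    @property
    def tier_counts(self) -> dict[str, int]:
        seen: dict[str, str] = {}
        for e in self.entries:
            seen[e.gene_id] = e.tier
        counts = {t: 0 for t in TIERS}
        for tier in seen.values():
            counts[tier] += 1
        return counts

    def genes(self, tier: str | None = None) -> list[str]:
        """Unique gene IDs, optionally restricted to one tier, in entry order."""
        out: list[str] = []
        for e in self.entries:
            if tier is not None and e.tier != tier:
                continue
            if e.gene_id not in out:
                out.append(e.gene_id)
        return out

    def regions_of(self, gene_id: str) -> list[str]:
        return [e.region_id for e in self.entries if e.gene_id == gene_id]

    def tier_of(self, gene_id: str) -> str | None:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e.tier
        return None

    def __len__(self) -> int:
        return len(self.entries)


def build_catalog(
    genes: Sequence[GeneRecord],
    regions: Sequence[Locus],
    phi_cutoff: float = PHI_CUTOFF,
    pts_cutoff: float = PTS_CUTOFF,
) -> QdsgCatalog:
    """Collect dosage-sensitive genes fully contained (by CDS) in risk regions.

    Output order follows the region list then gene position, so the catalog
    is invariant to the input order of ``genes``.
    """
    ordered = sorted(genes, key=lambda g: (g.chrom, g.cds_start, g.cds_end, g.gene_id))
    catalog = QdsgCatalog()
    seen: set[tuple[str, str]] = set()
    for region in regions:
        for gene in ordered:
            if not fully_contains(region, gene):
                continue
            tier = tier_dosage_sensitivity(gene.phi, gene.pts, phi_cutoff, pts_cutoff)
            if tier is None:
                continue
            key = (gene.gene_id, region.locus_id)
            if key in seen:
                continue
            seen.add(key)
            catalog.entries.append(QdsgEntry(gene.gene_id, region.locus_id, tier))
    return catalog
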