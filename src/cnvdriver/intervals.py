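"""Interval arithmetic: overlaps, union coverage, containment, carrier assignment.

Everything is 0-based half-open, so abutting intervals ([0,100) and
[100,200)) do not overlap.
"""

from __future__ import annotations

from typing import Iterable, Protocol, Sequence

import numpy as np

from cnvdriver.models import CnvCall, GeneRecord, Locus, SampleTable


class GenomicInterval(Protocol):
    chrom: str
    start: int
    end: int


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp between two intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)) — the symmetric overlap fraction."""
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans as a sorted list of disjoint spans."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def fraction_covered(
    query: GenomicInterval,
    others: Sequence[GenomicInterval],
    reciprocal: bool = False,
) -> float:
    """Fraction of ``query`` covered by the union of ``others`` (same chromosome).

    With ``reciprocal=True`` the statistic is instead the maximum pairwise
    reciprocal overlap between the query and any single other interval.
    """
    qlen = query.end - query.start
    if qlen <= 0:
        raise ValueError("zero-length query interval")
    same = [o for o in others if o.chrom == query.chrom]
    if reciprocal:
        return max((reciprocal_overlap(query, o) for o in same), default=0.0)
    covered = 0
    for s, e in merge_spans((o.start, o.end) for o in same):
        covered += max(0, min(e, query.end) - max(s, query.start))
    return covered / qlen


def fully_contains(region: Locus, gene: GeneRecord) -> bool:
    """True iff the gene CDS lies entirely within the region (bounds inclusive)."""
    return (
        region.chrom == gene.chrom
        and region.start <= gene.cds_start
        and gene.cds_end <= region.end
    )


class CarrierMatrix:
    """Which samples carry a qualifying CNV at each locus, per type and pooled.

    ``carriers[(locus_id, key)]`` is the set of carrier sample IDs, where
    ``key`` is "DEL", "DUP" or "ANY" (pooled). A sample with several
    qualifying CNVs at a locus is counted once.
    """

    POOLED = "ANY"

    def __init__(self, loci: Sequence[Locus], samples: SampleTable) -> None:
        self.locus_ids = [l.locus_id for l in loci]
        self.samples = samples
        self.carriers: dict[tuple[str, str], set[str]] = {
            (lid, key): set() for lid in self.locus_ids for key in ("DEL", "DUP", self.POOLED)
        }

    def add(self, locus_id: str, cnv_type: str, sample_id: str) -> None:
        self.carriers[(locus_id, cnv_type)].add(sample_id)
        self.carriers[(locus_id, self.POOLED)].add(sample_id)

    def is_carrier(self, locus_id: str, sample_id: str, cnv_type: str = POOLED) -> bool:
        return sample_id in self.carriers[(locus_id, cnv_type)]

    def counts(self, locus_id: str, cnv_type: str = POOLED) -> tuple[int, int, int, int]:
        """2x2 carrier counts (a, b, c, d) for one locus against the sample table."""
        carr = self.carriers[(locus_id, cnv_type)]
        a = sum(1 for s in self.samples.case_ids if s in carr)
        c = sum(1 for s in self.samples.control_ids if s in carr)
        return a, self.samples.n_cases - a, c, self.samples.n_controls - c


def assign_carriers(
    cnvs: Sequence[CnvCall],
    loci: Sequence[Locus],
    samples: SampleTable,
    min_overlap_bp: int = 1,
) -> CarrierMatrix:
    """Flag each (locus, sample) pair witnessed by >= min_overlap_bp of CNV overlap.

    A CNV whose sample is absent from the sample table is an error — silent
    phantom carriers would corrupt the contingency tables downstream.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    for cnv in cnvs:
        if cnv.sample_id not in samples:
            raise ValueError(f"CNV sample {cnv.sample_id!r} absent from sample table")

    matrix = CarrierMatrix(loci, samples)
    if not cnvs:
        return matrix

    # vectorize over CNVs, loop over loci (loci are few, CNVs many)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str], list[str]]] = {}
    for chrom in {c.chrom for c in cnvs}:
        sub = [c for c in cnvs if c.chrom == chrom]
        by_chrom[chrom] = (
            np.array([c.start for c in sub]),
            np.array([c.end for c in sub]),
            [c.cnv_type for c in sub],
            [c.sample_id for c in sub],
        )
    for locus in loci:
        if locus.chrom not in by_chrom:
            continue
        starts, ends, types, sids = by_chrom[locus.chrom]
        ov = np.minimum(ends, locus.end) - np.maximum(starts, locus.start)
        for idx in np.flatnonzero(ov >= min_overlap_bp):
            matrix.add(locus.locus_id, types[idx], sids[idx])
    return matrix
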