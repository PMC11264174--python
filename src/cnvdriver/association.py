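"""Locus-level case-control association: Fisher exact tests, Bonferroni
control, and novelty classification of significant loci against a reference
region list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import fisher_exact

from cnvdriver.intervals import assign_carriers, overlap_bp, reciprocal_overlap
from cnvdriver.models import AssociationResult, CnvCall, Locus, NoveltyCall, SampleTable


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample OR a*d/(b*c) with an explicit zero-cell policy.

    NaN when a margin is empty (either nobody or everybody is a carrier, or
    a study arm is empty): the OR is undefined. When at least one (but not
    all relevant) cell is zero, the Haldane-Anscombe +0.5 correction is
    applied to all four cells so the reported OR is finite.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in 2x2 table")
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return math.nan
    if min(a, b, c, d) == 0:
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return a * d / (b * c)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums the hypergeometric probabilities of all tables
    with the observed margins that are no more likely than the observed
    table (the minimum-likelihood convention). Returns (p_value,
    odds_ratio); the OR follows :func:`sample_odds_ratio`.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in 2x2 table")
    orat = sample_odds_ratio(a, b, c, d)
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return 1.0, orat  # degenerate margin: the observed table is the only table
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return min(p, 1.0), orat


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests, full precision."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


@dataclass
class RegionScanResult:
    """Per-locus pooled results plus per-type results and a CNV-type label.

    The primary test pools deletions and duplications ("a CNV in the
    region"); per-type tables are also tested and used to label each locus
    with the CNV type(s) whose case carrier frequency exceeds the control
    frequency.
    """

    pooled: list[AssociationResult]
    by_type: dict[str, list[AssociationResult]] = field(default_factory=dict)
    type_labels: dict[str, str] = field(default_factory=dict)

    @property
    def significant(self) -> list[AssociationResult]:
        return [r for r in self.pooled if r.significant]

    @property
    def nominal(self) -> list[AssociationResult]:
        return [r for r in self.pooled if r.nominal]


def _result(unit_id: str, a: int, b: int, c: int, d: int, threshold: float) -> AssociationResult:
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


def region_scan(
    cnvs: Sequence[CnvCall],
    loci: Sequence[Locus],
    samples: SampleTable,
    alpha: float = 0.05,
    min_overlap_bp: int = 1,
) -> RegionScanResult:
    """Fisher exact test of CNV carrier status at every locus.

    The Bonferroni denominator is the number of loci in the input table
    (all loci tested, not the subset with carriers). A locus is significant
    when p < alpha/n_loci and OR > 1; nominal when p < 0.05 and OR > 1.
    """
    if samples.n_cases == 0 or samples.n_controls == 0:
        raise ValueError("region_scan needs at least one case and one control")
    if not loci:
        raise ValueError("no loci to test")
    threshold = bonferroni_threshold(alpha, len(loci))
    matrix = assign_carriers(cnvs, loci, samples, min_overlap_bp=min_overlap_bp)

    pooled: list[AssociationResult] = []
    by_type: dict[str, list[AssociationResult]] = {"DEL": [], "DUP": []}
    type_labels: dict[str, str] = {}
    names = {"DEL": "deletion", "DUP": "duplication"}
    for locus in loci:
        pooled.append(_result(locus.locus_id, *matrix.counts(locus.locus_id), threshold))
        excess = []
        for t in ("DEL", "DUP"):
            a, b, c, d = matrix.counts(locus.locus_id, t)
            by_type[t].append(_result(f"{locus.locus_id}|{t}", a, b, c, d, threshold))
            n_case, n_ctrl = a + b, c + d
            if a / n_case > c / n_ctrl:
                excess.append(names[t])
        type_labels[locus.locus_id] = "-".join(excess)
    return RegionScanResult(pooled=pooled, by_type=by_type, type_labels=type_labels)


def classify_novelty(
    significant: Sequence[Locus],
    reference: Sequence[Locus],
    min_overlap_frac: float = 0.5,
) -> list[NoveltyCall]:
    """Label each significant locus against previously reported regions.

    known: reciprocal overlap >= min_overlap_frac with some reference
    region; boundary_expansion: some positive overlap but none reaching the
    threshold; novel: no overlap at all.
    """
    if not (0.0 < min_overlap_frac <= 1.0):
        raise ValueError("min_overlap_frac must be in (0, 1]")
    calls: list[NoveltyCall] = []
    for locus in significant:
        touching = [r for r in reference if overlap_bp(locus, r) > 0]
        if not touching:
            calls.append(NoveltyCall(locus.locus_id, "novel"))
            continue
        matched = tuple(r.locus_id for r in touching)
        if any(reciprocal_overlap(locus, r) >= min_overlap_frac for r in touching):
            calls.append(NoveltyCall(locus.locus_id, "known", matched))
        else:
            calls.append(NoveltyCall(locus.locus_id, "boundary_expansion", matched))
    return calls
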