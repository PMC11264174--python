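"""Gene-phenotype association over CNV-carrier patients.

For each gene with carriers, each phenotype term observed in those
carriers is an evaluated pair; pairs whose incidence among the gene's
carriers exceeds the population incidence are tested with a two-sided
Fisher exact test of carriers vs non-carrier patients. The Bonferroni
denominator is the number of evaluated pairs (pre-direction-filter) —
that is the reading fixed by the published threshold arithmetic
(0.05 / 40,838 ~ 1.22e-6).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from cnvdriver.association import bonferroni_threshold, fisher_exact_two_sided
from cnvdriver.models import AssociationResult, PhenotypeTable


def population_incidence(phenotypes: PhenotypeTable) -> dict[str, float]:
    """Per-term incidence over all patients in the table."""
    n = len(phenotypes)
    if n == 0:
        raise ValueError("empty phenotype table")
    counts: dict[str, int] = {}
    for terms in phenotypes.terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: c / n for t, c in counts.items()}


def phenotype_frequencies(
    carriers: Mapping[str, Sequence[str]],
    phenotypes: PhenotypeTable,
) -> dict[tuple[str, str], float]:
    """Incidence of each term among each gene's carrier patients.

    incidence(gene, term) = carriers of the gene with the term / carriers
    of the gene. Genes with zero carriers are excluded. Only (gene, term)
    pairs with at least one carrier showing the term are returned — these
    are the pairs the scan evaluates.
    """
    out: dict[tuple[str, str], float] = {}
    for gene, patients in carriers.items():
        pts = [p for p in dict.fromkeys(patients) if p in phenotypes.terms]
        if not pts:
            continue
        term_counts: dict[str, int] = {}
        for p in pts:
            for t in phenotypes.terms[p]:
                term_counts[t] = term_counts.get(t, 0) + 1
        for t, c in term_counts.items():
            out[(gene, t)] = c / len(pts)
    return out


def phenotype_scan(
    carriers: Mapping[str, Sequence[str]],
    phenotypes: PhenotypeTable,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Fisher scan of gene-phenotype pairs with carrier incidence above background.

    2x2 layout per pair: gene carriers with/without the term vs non-carrier
    patients with/without the term (carriers of other genes stay in the
    comparison group). Results are returned only for direction-passing
    pairs; the Bonferroni threshold uses the full evaluated-pair count.
    """
    if not any(p in phenotypes.terms for pts in carriers.values() for p in pts):
        raise ValueError("carrier patients are disjoint from the phenotype table")
    pop = population_incidence(phenotypes)
    freqs = phenotype_frequencies(carriers, phenotypes)
    n_evaluated = len(freqs)
    threshold = bonferroni_threshold(alpha, n_evaluated)

    all_patients = set(phenotypes.terms)
    results: list[AssociationResult] = []
    for (gene, term), inc in freqs.items():
        if inc <= pop[term]:
            continue
        carr = {p for p in carriers[gene] if p in all_patients}
        a = sum(1 for p in carr if phenotypes.has_term(p, term))
        b = len(carr) - a
        non_carr = all_patients - carr
        c = sum(1 for p in non_carr if phenotypes.has_term(p, term))
        d = len(non_carr) - c
        p_val, orat = fisher_exact_two_sided(a, b, c, d)
        or_gt_1 = (not math.isnan(orat)) and orat > 1.0
        results.append(
            AssociationResult(
                unit_id=f"{gene}|{term}",
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=orat,
                p_value=p_val,
                bonferroni_threshold=threshold,
                significant=bool(p_val < threshold and or_gt_1),
                nominal=bool(p_val < 0.05 and or_gt_1),
            )
        )
    return results
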