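"""Two-sided Fisher gene-set (and term-set) over-representation tests.

The universe must be supplied explicitly — there is no defensible default,
and the choice changes the answer, so omission is an error rather than a
guess. The target set is intersected with the universe before testing.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from cnvdriver.association import bonferroni_threshold, fisher_exact_two_sided
from cnvdriver.models import AssociationResult, GeneSetCatalog


def gene_set_enrichment(
    query: Iterable[str],
    target_set: Iterable[str],
    universe: Iterable[str],
    unit_id: str = "enrichment",
    alpha: float = 0.05,
    n_tests: int = 1,
) -> AssociationResult:
    """Fisher test of query/target overlap within an explicit gene universe.

    2x2 layout: a = |query & target|, b = |query - target|,
    c = |target - query| (within the universe), d = the rest of the universe.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty universe")
    q = set(map(str, query))
    if not q <= uni:
        missing = sorted(q - uni)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {missing}")
    t = set(map(str, target_set)) & uni
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(uni) - a - b - c
    p, orat = fisher_exact_two_sided(a, b, c, d)
    threshold = bonferroni_threshold(alpha, n_tests)
    or_gt_1 = orat == orat and orat > 1.0  # NaN-safe
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


def term_overlap_test(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    term_universe: Iterable[str],
    unit_id: str = "term_overlap",
) -> AssociationResult:
    """Same 2x2 construction over term IDs instead of gene IDs."""
    return gene_set_enrichment(terms_a, terms_b, term_universe, unit_id=unit_id)


def catalog_enrichment(
    query: Iterable[str],
    catalog: GeneSetCatalog | Mapping[str, Sequence[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Test the query against every set in a GMT-like catalog.

    Bonferroni correction is over the number of sets tested, mirroring how
    GO-style enrichment corrects over its term catalog.
    """
    sets = catalog.sets if isinstance(catalog, GeneSetCatalog) else dict(catalog)
    if not sets:
        raise ValueError("empty gene-set catalog")
    uni = list(universe)
    return [
        gene_set_enrichment(query, genes, uni, unit_id=name, alpha=alpha, n_tests=len(sets))
        for name, genes in sets.items()
    ]
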