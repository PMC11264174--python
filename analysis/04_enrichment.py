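#!/usr/bin/env python
"""Test qDSG overlap with reference gene catalogs (SFARI/GeneTrek-style).

Builds a mock known-risk-gene catalog that half-overlaps the qDSG list,
runs the two-sided Fisher over-representation test against the full
annotation as universe, and writes results/enrichment.tsv. The qDSG list
should be strongly enriched by construction.
"""

from pathlib import Path

from cnvdriver import io as cio
from cnvdriver.enrichment import catalog_enrichment
from cnvdriver.simulate import stream_rng

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def read_catalog_genes(path):
    rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
    genes = []
    for g, _r, _t in rows:
        if g not in genes:
            genes.append(g)
    return genes


def main() -> None:
    universe = [g.gene_id for g in cio.read_gene_table(BASE / "synthetic" / "genes.tsv")]
    qdsg = read_catalog_genes(BASE / "qdsg_catalog.tsv")
    rng = stream_rng(SEED, "analysis.reference_sets")
    known = sorted(set(qdsg[: len(qdsg) // 2])
                   | {universe[i] for i in rng.choice(len(universe), 30, replace=False)})
    results = catalog_enrichment(qdsg, {"known_risk_genes": known}, universe)
    cio.write_results(results, BASE / "enrichment.tsv")
    r = results[0]
    print(f"{r.a} of {len(qdsg)} qDSGs in the {len(known)}-gene reference catalog "
          f"(universe {len(universe)}): OR={r.odds_ratio:.2f}, p={r.p_value:.3g}")


if __name__ == "__main__":
    main()
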