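#!/usr/bin/env python
"""Build the qDSG catalog: dosage-sensitive genes inside significant loci.

Genes whose CDS is fully contained in a Bonferroni-significant risk locus
are tiered by their dosage-sensitivity scores (HI: pHI >= 0.84; TS:
pTS >= 0.993; bHITS: both). Writes results/qdsg_catalog.tsv.
"""

from pathlib import Path

from cnvdriver import io as cio
from cnvdriver.catalog import build_catalog

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genes = cio.read_gene_table(BASE / "synthetic" / "genes.tsv")
    regions = cio.read_loci(BASE / "significant_loci.tsv")
    cat = build_catalog(genes, regions)
    with open(BASE / "qdsg_catalog.tsv", "w") as fh:
        fh.write("gene_id\tregion_id\ttier\n")
        for e in cat.entries:
            fh.write(f"{e.gene_id}\t{e.region_id}\t{e.tier}\n")
    counts = cat.tier_counts
    total = sum(counts.values())
    print(f"{len(genes)} genes, {len(regions)} significant regions -> "
          f"{total} qDSGs ({counts['HI']} HI, {counts['TS']} TS, {counts['bHITS']} bHITS)")


if __name__ == "__main__":
    main()
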