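#!/usr/bin/env python
"""Generate the synthetic study inputs every downstream driver consumes.

Writes, under results/synthetic/: a case-control CNV cohort (2,000 + 2,000
samples, 40 loci of which 4 carry planted deletion risk at control carrier
frequency 0.01 and OR 10), a gene annotation with planted HI/TS/bHITS
fractions, 493 multiplex families transmitting HI-gene deletions at
probability 0.726, Brain-Span-like expression counts with the qDSGs planted
in the top tail, and a phenotype table with three planted gene-phenotype
effects. All of it is deterministic for the seed below.
"""

from pathlib import Path

from cnvdriver.pipeline import run_pipeline

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    out = run_pipeline({"seed": SEED, "stages": ["simulate"]}, out_dir=OUT)
    print(f"wrote synthetic cohort, annotation and loci under {out}/")
    for f in sorted(out.glob("*.tsv")):
        n = sum(1 for _ in open(f)) - 1
        print(f"  {f.name}: {n} rows")


if __name__ == "__main__":
    main()
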