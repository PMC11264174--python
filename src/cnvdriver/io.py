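"""Readers and writers for every tabular format the pipeline touches.

Column orders are documented in FORMATS.md. All readers validate and fail
with the offending line number instead of silently coercing; all writers
emit a header line (PED and GMT, whose dialects forbid one, excepted);
read(write(x)) == x for every format. Coordinates are 0-based half-open
on disk and in memory.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from cnvdriver.expression import ExpressionMatrix
from cnvdriver.models import (
    AssociationResult,
    CnvCall,
    GeneRecord,
    GeneSetCatalog,
    Locus,
    Pedigree,
    PedigreeMember,
    PhenotypeTable,
    SampleTable,
    _PED_PHENO,
    _PED_PHENO_OUT,
)

MISSING = "."


class FormatError(ValueError):
    def __init__(self, path: Path | str, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _rows(path: Path | str, expect_header: str | None = None):
    """Yield (line_no, fields) for non-empty lines; checks the header if given."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if i == 1 and expect_header is not None:
                got = "\t".join(fields)
                if got != expect_header:
                    raise FormatError(path, 1, f"expected header {expect_header!r}, got {got!r}")
                continue
            yield i, fields


def _parse_int(path, line_no, value, what) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(path, line_no, f"{what} {value!r} is not an integer") from None


def _parse_float(path, line_no, value, what) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(path, line_no, f"{what} {value!r} is not a number") from None


# ---------------------------------------------------------------- CNV calls

CNV_HEADER = "chrom\tstart\tend\tsample_id\tscore\tstrand\tcnv_type\taf"


def read_cnv_bed(path: Path | str) -> list[CnvCall]:
    """Read CNV calls from BED-like TSV.

    Two dialects (see FORMATS.md): the minimal 5-column form
    (chrom, start, end, sample_id, cnv_type) and the written 8-column form
    (chrom, start, end, sample_id, score='.', strand='.', cnv_type, af)
    with a header line. '.' codes a missing allele frequency.
    """
    calls: list[CnvCall] = []
    for line_no, f in _rows(path):
        if line_no == 1 and f[0] == "chrom":
            continue  # header of the 8-column dialect
        if len(f) == 5:
            chrom, start, end, sample_id, cnv_type = f
            af_field = MISSING
        elif len(f) == 8:
            chrom, start, end, sample_id, _score, _strand, cnv_type, af_field = f
        else:
            raise FormatError(path, line_no, f"expected 5 or 8 columns, got {len(f)}")
        start_i = _parse_int(path, line_no, start, "start")
        end_i = _parse_int(path, line_no, end, "end")
        af = None if af_field == MISSING else _parse_float(path, line_no, af_field, "af")
        try:
            calls.append(CnvCall(chrom, start_i, end_i, cnv_type, sample_id, af))
        except ValueError as exc:
            raise FormatError(path, line_no, str(exc)) from None
    return calls


def write_cnv_bed(calls: Sequence[CnvCall], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(CNV_HEADER + "\n")
        for c in calls:
            af = MISSING if c.af is None else repr(c.af)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample_id}\t.\t.\t{c.cnv_type}\t{af}\n"
            )


# ---------------------------------------------------------------- loci

LOCI_HEADER = "locus_id\tchrom\tstart\tend"


def read_loci(path: Path | str) -> list[Locus]:
    loci: list[Locus] = []
    seen: set[str] = set()
    for line_no, f in _rows(path, expect_header=LOCI_HEADER):
        if len(f) != 4:
            raise FormatError(path, line_no, f"expected 4 columns, got {len(f)}")
        lid = f[0]
        if lid in seen:
            raise FormatError(path, line_no, f"duplicate locus_id {lid!r}")
        seen.add(lid)
        try:
            loci.append(
                Locus(lid, f[1], _parse_int(path, line_no, f[2], "start"),
                      _parse_int(path, line_no, f[3], "end"))
            )
        except ValueError as exc:
            raise FormatError(path, line_no, str(exc)) from None
    return loci


def write_loci(loci: Sequence[Locus], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(LOCI_HEADER + "\n")
        for l in loci:
            fh.write(f"{l.locus_id}\t{l.chrom}\t{l.start}\t{l.end}\n")


# ---------------------------------------------------------------- genes

GENE_HEADER = "gene_id\tchrom\tcds_start\tcds_end\tphi\tpts"


def read_gene_table(path: Path | str) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for line_no, f in _rows(path, expect_header=GENE_HEADER):
        if len(f) != 6:
            raise FormatError(path, line_no, f"expected 6 columns, got {len(f)}")
        if f[0] in seen:
            raise FormatError(path, line_no, f"duplicate gene_id {f[0]!r}")
        seen.add(f[0])
        try:
            genes.append(
                GeneRecord(
                    f[0], f[1],
                    _parse_int(path, line_no, f[2], "cds_start"),
                    _parse_int(path, line_no, f[3], "cds_end"),
                    _parse_float(path, line_no, f[4], "phi"),
                    _parse_float(path, line_no, f[5], "pts"),
                )
            )
        except ValueError as exc:
            raise FormatError(path, line_no, str(exc)) from None
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(GENE_HEADER + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.cds_start}\t{g.cds_end}\t{g.phi!r}\t{g.pts!r}\n"
            )


# ---------------------------------------------------------------- samples

SAMPLE_HEADER = "sample_id\tstatus\tcohort"


def read_samples(path: Path | str) -> SampleTable:
    status: dict[str, str] = {}
    cohort: dict[str, str] = {}
    for line_no, f in _rows(path, expect_header=SAMPLE_HEADER):
        if len(f) != 3:
            raise FormatError(path, line_no, f"expected 3 columns, got {len(f)}")
        sid, lab, coh = f
        if sid in status:
            raise FormatError(path, line_no, f"duplicate sample_id {sid!r}")
        if lab not in ("case", "control"):
            raise FormatError(path, line_no, f"status {lab!r} is not 'case'/'control'")
        status[sid] = lab
        if coh != MISSING:
            cohort[sid] = coh
    return SampleTable(status, cohort)


def write_samples(samples: SampleTable, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(SAMPLE_HEADER + "\n")
        for sid, lab in samples.status.items():
            fh.write(f"{sid}\t{lab}\t{samples.cohort.get(sid, MISSING)}\n")


# ---------------------------------------------------------------- PED

def read_ped(path: Path | str) -> Pedigree:
    """Whitespace-delimited 6-column PED: FID IID PAT MAT SEX PHENO.

    Phenotype uses the PLINK coding (2 affected, 1 unaffected, 0/-9
    unknown). No header line.
    """
    members: list[PedigreeMember] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 6:
                raise FormatError(path, line_no, f"expected 6 PED columns, got {len(f)}")
            fid, iid, pat, mat, sex, pheno = f
            if pheno not in _PED_PHENO:
                raise FormatError(path, line_no, f"bad phenotype code {pheno!r}")
            if sex not in ("0", "1", "2"):
                raise FormatError(path, line_no, f"bad sex code {sex!r}")
            members.append(PedigreeMember(fid, iid, pat, mat, sex, _PED_PHENO[pheno]))
    try:
        return Pedigree(members)
    except ValueError as exc:
        raise FormatError(path, 0, str(exc)) from None


def write_ped(pedigree: Pedigree, path: Path | str) -> None:
    with open(path, "w") as fh:
        for m in pedigree.members:
            fh.write(
                f"{m.family_id}\t{m.individual_id}\t{m.father_id}\t{m.mother_id}"
                f"\t{m.sex}\t{_PED_PHENO_OUT[m.affected]}\n"
            )


# ---------------------------------------------------------------- GMT

def read_gmt(path: Path | str) -> GeneSetCatalog:
    """GMT: set name, description, then one gene per column. No header."""
    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    for line_no, f in _rows(path):
        if len(f) < 3:
            raise FormatError(path, line_no, "GMT line needs name, description and >=1 gene")
        name, desc, genes = f[0], f[1], [g for g in f[2:] if g]
        if name in sets:
            raise FormatError(path, line_no, f"duplicate set name {name!r}")
        if not genes:
            raise FormatError(path, line_no, f"gene set {name!r} is empty")
        sets[name] = genes
        descs[name] = desc
    return GeneSetCatalog(sets, descs)


def write_gmt(catalog: GeneSetCatalog, path: Path | str) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.sets.items():
            desc = catalog.descriptions.get(name, MISSING)
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------- phenotypes

PHENO_HEADER = "patient_id\tterm_id"


def read_phenotypes(path: Path | str) -> PhenotypeTable:
    """Long-form TSV: one (patient, term) per row; '.' codes a patient with no terms."""
    terms: dict[str, list[str]] = {}
    for line_no, f in _rows(path, expect_header=PHENO_HEADER):
        if len(f) != 2:
            raise FormatError(path, line_no, f"expected 2 columns, got {len(f)}")
        pid, term = f
        terms.setdefault(pid, [])
        if term != MISSING:
            if term in terms[pid]:
                raise FormatError(path, line_no, f"duplicate term {term!r} for patient {pid!r}")
            terms[pid].append(term)
    return PhenotypeTable(terms)


def write_phenotypes(table: PhenotypeTable, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(PHENO_HEADER + "\n")
        for pid, tlist in table.terms.items():
            if not tlist:
                fh.write(f"{pid}\t{MISSING}\n")
            for t in tlist:
                fh.write(f"{pid}\t{t}\n")


# ---------------------------------------------------------------- expression

def read_expression(counts_path: Path | str, meta_path: Path | str) -> ExpressionMatrix:
    """Genes x samples count TSV plus a sample metadata TSV (stage, brain_region)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts, meta)


def write_expression(em: ExpressionMatrix, counts_path: Path | str, meta_path: Path | str) -> None:
    em.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    em.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------- results

RESULT_HEADER = (
    "unit_id\ta\tb\tc\td\todds_ratio\tp_value\tbonferroni_threshold\tsignificant\tnominal"
)


def read_results(path: Path | str) -> list[AssociationResult]:
    out: list[AssociationResult] = []
    for line_no, f in _rows(path, expect_header=RESULT_HEADER):
        if len(f) != 10:
            raise FormatError(path, line_no, f"expected 10 columns, got {len(f)}")
        try:
            out.append(
                AssociationResult(
                    unit_id=f[0],
                    a=_parse_int(path, line_no, f[1], "a"),
                    b=_parse_int(path, line_no, f[2], "b"),
                    c=_parse_int(path, line_no, f[3], "c"),
                    d=_parse_int(path, line_no, f[4], "d"),
                    odds_ratio=math.nan if f[5] == "NA" else _parse_float(path, line_no, f[5], "odds_ratio"),
                    p_value=_parse_float(path, line_no, f[6], "p_value"),
                    bonferroni_threshold=_parse_float(path, line_no, f[7], "bonferroni_threshold"),
                    significant={"True": True, "False": False}[f[8]],
                    nominal={"True": True, "False": False}[f[9]],
                )
            )
        except KeyError:
            raise FormatError(path, line_no, "significant/nominal must be True or False") from None
        except ValueError as exc:
            raise FormatError(path, line_no, str(exc)) from None
    return out


def write_results(results: Sequence[AssociationResult], path: Path | str) -> None:
    """Write association results as TSV; NaN odds ratios are written as NA.

    Floats use repr so the round trip is exact.
    """
    with open(path, "w") as fh:
        fh.write(RESULT_HEADER + "\n")
        for r in results:
            orat = "NA" if math.isnan(r.odds_ratio) else repr(r.odds_ratio)
            fh.write(
                f"{r.unit_id}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{orat}\t{r.p_value!r}"
                f"\t{r.bonferroni_threshold!r}\t{r.significant}\t{r.nominal}\n"
            )


# ---------------------------------------------------------------- edge lists

EDGE_HEADER = "gene_a\tgene_b\tscore"


def read_edge_list(path: Path | str) -> list[tuple[str, str, float]]:
    edges: list[tuple[str, str, float]] = []
    for line_no, f in _rows(path, expect_header=EDGE_HEADER):
        if len(f) != 3:
            raise FormatError(path, line_no, f"expected 3 columns, got {len(f)}")
        score = _parse_float(path, line_no, f[2], "score")
        if not (0.0 <= score <= 1.0):
            raise FormatError(path, line_no, f"score {score} outside [0, 1]")
        edges.append((f[0], f[1], score))
    return edges


def write_edge_list(edges: Sequence[tuple[str, str, float]], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(EDGE_HEADER + "\n")
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s!r}\n")
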