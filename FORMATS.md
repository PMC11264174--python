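# File formats

All files are tab-separated text. Genomic coordinates are **0-based,
half-open** (BED convention) everywhere, on disk and in memory.
Chromosome names are normalized on read by stripping a leading `chr`.
Every reader rejects malformed rows with the offending line number;
every writer emits a header line except PED and GMT, whose standard
dialects have none. `.` codes a missing value. For every format,
`read(write(x)) == x`.

## CNV calls (`read_cnv_bed` / `write_cnv_bed`)

Written dialect (8 columns, header line):

    chrom  start  end  sample_id  score  strand  cnv_type  af

`score` and `strand` are always `.` (CNVs are unstranded); `cnv_type` is
`DEL` or `DUP`; `af` is an allele frequency in [0, 1] or `.`.
A minimal headerless 5-column dialect is also accepted on read:

    chrom  start  end  sample_id  cnv_type

## Loci (`read_loci` / `write_loci`)

    locus_id  chrom  start  end

`locus_id` (cytoband-style name) must be unique.

## Gene table (`read_gene_table` / `write_gene_table`)

    gene_id  chrom  cds_start  cds_end  phi  pts

`phi` (pHI) and `pts` (pTS) are scores in [0, 1]; the CDS is a single
span per gene.

## Sample table (`read_samples` / `write_samples`)

    sample_id  status  cohort

`status` is `case` or `control`; `cohort` is a free label or `.`.

## Pedigree (`read_ped` / `write_ped`)

Standard 6-column PED, whitespace-delimited, no header:

    FID  IID  PAT  MAT  SEX  PHENO

`PAT`/`MAT` are `0` when missing; `SEX` is 1 male / 2 female / 0 unknown;
`PHENO` uses the PLINK coding 2 = affected, 1 = unaffected, 0 or -9 =
unknown.

## Gene sets (`read_gmt` / `write_gmt`)

Standard GMT: one set per line — name, description, then one gene per
column. Sets must be non-empty.

## Phenotypes (`read_phenotypes` / `write_phenotypes`)

Long form, one `(patient, term)` pair per row:

    patient_id  term_id

A patient with no terms is kept with a single `.` term row. Term lists
are deduplicated.

## Expression (`read_expression` / `write_expression`)

Two files: a genes × samples count matrix (first column `gene_id`, one
column per sample) and a sample metadata table:

    sample_id  stage  brain_region

## Association results (`read_results` / `write_results`)

    unit_id  a  b  c  d  odds_ratio  p_value  bonferroni_threshold  significant  nominal

`a..d` are the 2×2 counts (case-carrier, case-noncarrier,
control-carrier, control-noncarrier); `odds_ratio` is `NA` when
undefined; flags are `True`/`False`. Floats are written with full
precision (`repr`) so round trips are exact.

## Interaction edge list (`read_edge_list` / `write_edge_list`)

    gene_a  gene_b  score

`score` is a combined interaction confidence in [0, 1].
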