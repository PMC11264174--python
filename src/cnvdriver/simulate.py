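"""Synthetic cohorts, families, annotations, expression and phenotypes.

Each generator emulates the statistical structure one pipeline stage
assumes, so the whole pipeline is testable without clinical data:

* case-control cohorts with planted risk loci of specified control
  carrier frequency f and odds ratio OR — case carrier frequency is the
  odds transform f_case = OR*f / (1 - f + OR*f);
* multiplex families in which a carrier parent transmits a deletion to
  each affected child independently with a specified probability;
* gene annotations with exact planted fractions of HI / TS / bHITS genes
  (scores drawn uniformly inside the tier-defining boxes);
* negative-binomial expression counts with a planted highly-expressed set;
* phenotype tables with planted gene-phenotype incidences over a
  background incidence.

Randomness: every generator derives its own independent stream from
(seed, CRC32 of the stream name), so adding one generator call never
perturbs another, and a fixed seed gives byte-identical outputs.
Background CNVs are rejection-sampled to never intersect risk loci,
making planted effects the only case-control signal; each planted carrier
gets exactly one CNV spanning the full locus (the counting code must —
and does — still tolerate multi-CNV carriers arising in real data).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cnvdriver.models import (
    AFFECTED,
    PED_MISSING,
    UNAFFECTED,
    CnvCall,
    GeneRecord,
    Locus,
    Pedigree,
    PedigreeMember,
    PhenotypeTable,
    SampleTable,
)
from cnvdriver.catalog import PHI_CUTOFF, PTS_CUTOFF

# autosome lengths in Mb (hg38, rounded) — the coordinate space for
# background events
GENOME_MB = {
    "1": 248, "2": 242, "3": 198, "4": 190, "5": 181, "6": 171, "7": 159,
    "8": 145, "9": 138, "10": 134, "11": 135, "12": 133, "13": 114,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 64, "21": 47, "22": 51,
}


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream keyed by (seed, CRC32 of the stream name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def case_carrier_freq(f_controls: float, odds_ratio: float) -> float:
    """Carrier frequency in cases implied by a control frequency and an OR."""
    if not (0.0 < f_controls < 1.0):
        raise ValueError(f"carrier frequency {f_controls} outside (0, 1)")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio {odds_ratio} must be positive")
    return odds_ratio * f_controls / (1.0 - f_controls + odds_ratio * f_controls)


@dataclass
class CohortSpec:
    """Design of a synthetic case-control CNV cohort."""

    n_cases: int
    n_controls: int
    loci: list[Locus]
    # locus_id -> (carrier frequency in controls, odds ratio)
    risk_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    background_cnv_rate: float = 0.5  # Poisson mean per sample
    cnv_type_mix: float = 0.5  # P(background event is DEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be >= 0")
        known = {l.locus_id for l in self.loci}
        for lid, (f, orat) in self.risk_effects.items():
            if lid not in known:
                raise ValueError(f"risk effect for unknown locus {lid!r}")
            case_carrier_freq(f, orat)  # validates f and OR
        if not (0.0 <= self.cnv_type_mix <= 1.0):
            raise ValueError("cnv_type_mix must be in [0, 1]")
        if self.background_cnv_rate < 0:
            raise ValueError("background_cnv_rate must be >= 0")


def generate_cohort(spec: CohortSpec) -> tuple[list[CnvCall], SampleTable]:
    """Simulate CNV calls and case/control labels for a cohort.

    Each planted carrier receives one deletion spanning its risk locus
    exactly; background events (type drawn from cnv_type_mix, length
    log-uniform 20 kb – 2 Mb) are placed uniformly on the autosomes and
    rejection-sampled away from all risk loci.
    """
    ids = [f"case{i + 1:05d}" for i in range(spec.n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(spec.n_controls)
    ]
    status = {s: ("case" if s.startswith("case") else "control") for s in ids}
    samples = SampleTable(status)

    calls: list[CnvCall] = []
    rng_plant = stream_rng(spec.seed, "cohort.planted")
    is_case = np.array([s.startswith("case") for s in ids])
    for locus in spec.loci:
        if locus.locus_id not in spec.risk_effects:
            continue
        f, orat = spec.risk_effects[locus.locus_id]
        f_case = case_carrier_freq(f, orat)
        probs = np.where(is_case, f_case, f)
        carriers = rng_plant.random(len(ids)) < probs
        for idx in np.flatnonzero(carriers):
            calls.append(
                CnvCall(locus.chrom, locus.start, locus.end, "DEL", ids[idx])
            )

    rng_bg = stream_rng(spec.seed, "cohort.background")
    if spec.background_cnv_rate > 0 and ids:
        chroms = list(GENOME_MB)
        lengths = np.array([GENOME_MB[c] for c in chroms], dtype=float)
        chrom_p = lengths / lengths.sum()
        n_events = rng_bg.poisson(spec.background_cnv_rate, size=len(ids))
        loci_by_chrom: dict[str, list[Locus]] = {}
        for l in spec.loci:
            loci_by_chrom.setdefault(l.chrom, []).append(l)
        for sidx, k in enumerate(n_events):
            for _ in range(k):
                for _try in range(1000):
                    ci = rng_bg.choice(len(chroms), p=chrom_p)
                    chrom = chroms[ci]
                    length = int(round(10 ** rng_bg.uniform(np.log10(2e4), np.log10(2e6))))
                    start = int(rng_bg.integers(0, GENOME_MB[chrom] * 1_000_000 - length))
                    end = start + length
                    if all(
                        min(end, l.end) - max(start, l.start) <= 0
                        for l in loci_by_chrom.get(chrom, [])
                    ):
                        break
                else:  # pragma: no cover - loci would have to tile a chromosome
                    raise RuntimeError("could not place a background CNV off the risk loci")
                cnv_type = "DEL" if rng_bg.random() < spec.cnv_type_mix else "DUP"
                calls.append(CnvCall(chrom, start, end, cnv_type, ids[sidx]))
    return calls, samples


def generate_gene_annotation(
    n_genes: int,
    region_layout: Sequence[Locus],
    hi_frac: float,
    ts_frac: float,
    bhits_frac: float,
    seed: int = 0,
) -> list[GeneRecord]:
    """Genes with planted dosage-sensitivity tiers inside the given regions.

    Tier counts are allocated deterministically (round(frac * n), not
    sampled), scores are drawn uniformly inside each tier's (pHI, pTS)
    box, and every CDS lies fully inside its parent region (genes are
    dealt to regions round-robin). Genes sharing a region are tiled into
    disjoint slots so no two CDS spans overlap — mirroring real
    annotations, where overlapping coding spans are the rare exception.
    """
    if min(hi_frac, ts_frac, bhits_frac) < 0 or hi_frac + ts_frac + bhits_frac > 1:
        raise ValueError("tier fractions must be >= 0 and sum to <= 1")
    if not region_layout:
        raise ValueError("need at least one region to place genes in")
    n_hi = round(hi_frac * n_genes)
    n_ts = round(ts_frac * n_genes)
    n_b = round(bhits_frac * n_genes)
    tiers = ["HI"] * n_hi + ["TS"] * n_ts + ["bHITS"] * n_b
    tiers += [None] * (n_genes - len(tiers))

    rng = stream_rng(seed, "genes")
    eps = 1e-9  # keeps strict-side draws off the cutoff boundary
    boxes = {
        "HI": ((PHI_CUTOFF, 1.0), (0.0, PTS_CUTOFF - eps)),
        "TS": ((0.0, PHI_CUTOFF - eps), (PTS_CUTOFF, 1.0)),
        "bHITS": ((PHI_CUTOFF, 1.0), (PTS_CUTOFF, 1.0)),
        None: ((0.0, PHI_CUTOFF - eps), (0.0, PTS_CUTOFF - eps)),
    }
    n_regions = len(region_layout)
    per_region = [len(range(r, n_genes, n_regions)) for r in range(n_regions)]
    genes: list[GeneRecord] = []
    for i, tier in enumerate(tiers):
        region = region_layout[i % n_regions]
        (phi_lo, phi_hi), (pts_lo, pts_hi) = boxes[tier]
        phi = float(rng.uniform(phi_lo, phi_hi))
        pts = float(rng.uniform(pts_lo, pts_hi))
        # disjoint slot for this gene within its region
        slot_len = region.length // max(per_region[i % n_regions], 1)
        if slot_len < 2:
            raise ValueError(
                f"region {region.locus_id} too small for {per_region[i % n_regions]} genes"
            )
        slot_start = region.start + (i // n_regions) * slot_len
        cds_len = int(rng.integers(1, slot_len))
        cds_start = slot_start + int(rng.integers(0, slot_len - cds_len + 1))
        genes.append(
            GeneRecord(
                gene_id=f"G{i + 1:05d}",
                chrom=region.chrom,
                cds_start=cds_start,
                cds_end=cds_start + cds_len,
                phi=phi,
                pts=pts,
            )
        )
    return genes


@dataclass
class FamilySpec:
    """Design of a synthetic multiplex-family deletion study."""

    n_families: int
    n_affected_children_range: tuple[int, int] = (2, 3)
    transmission_prob: float = 0.5
    carrier_parent_freq: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_affected_children_range
        if not (1 <= lo <= hi):
            raise ValueError("need 1 <= min children <= max children")
        if not (0.0 <= self.transmission_prob <= 1.0):
            raise ValueError("transmission_prob must be in [0, 1]")
        if not (0.0 <= self.carrier_parent_freq <= 1.0):
            raise ValueError("carrier_parent_freq must be in [0, 1]")


def generate_multiplex_families(
    spec: FamilySpec,
    target_genes: Sequence[GeneRecord],
) -> tuple[Pedigree, list[CnvCall]]:
    """Families in which carrier parents transmit gene deletions to affected children.

    Each parent is a carrier with probability carrier_parent_freq, carries
    a deletion fully covering the CDS of one target gene (chosen at
    random), and transmits it to each affected child independently with
    probability transmission_prob. Parents are unaffected; all children
    are affected (the test only counts affected offspring).
    """
    if not target_genes:
        raise ValueError("target_genes is empty")
    rng = stream_rng(spec.seed, "families")
    members: list[PedigreeMember] = []
    calls: list[CnvCall] = []
    lo, hi = spec.n_affected_children_range
    for fi in range(spec.n_families):
        fid = f"fam{fi + 1:04d}"
        father, mother = f"{fid}_fa", f"{fid}_mo"
        members.append(PedigreeMember(fid, father, PED_MISSING, PED_MISSING, "1", UNAFFECTED))
        members.append(PedigreeMember(fid, mother, PED_MISSING, PED_MISSING, "2", UNAFFECTED))
        parent_call: dict[str, CnvCall] = {}
        for pid in (father, mother):
            if rng.random() < spec.carrier_parent_freq:
                gene = target_genes[int(rng.integers(0, len(target_genes)))]
                pad = int(rng.integers(100, 5000))
                call = CnvCall(
                    gene.chrom, max(gene.cds_start - pad, 0), gene.cds_end + pad, "DEL", pid
                )
                parent_call[pid] = call
                calls.append(call)
        n_children = int(rng.integers(lo, hi + 1))
        for ci in range(n_children):
            cid = f"{fid}_c{ci + 1}"
            sex = "1" if ci % 2 == 0 else "2"
            members.append(PedigreeMember(fid, cid, father, mother, sex, AFFECTED))
            for pid, call in parent_call.items():
                if rng.random() < spec.transmission_prob:
                    # an inherited CNV is the parent's event: same coordinates
                    calls.append(
                        CnvCall(call.chrom, call.start, call.end, "DEL", cid)
                    )
    return Pedigree(members), calls


def generate_expression(
    n_genes: int,
    strata: Sequence[tuple[str, str]],
    planted_top_set: Sequence[str],
    nb_mean: float = 50.0,
    nb_dispersion: float = 0.3,
    seed: int = 0,
    samples_per_stratum: int = 4,
):
    """Negative-binomial counts with a planted highly-expressed gene set.

    Baseline gene means are uniform in [0.5, 2] x nb_mean; planted genes
    get 20 x nb_mean in every stratum, parking them in the top tail
    everywhere. The NB is parametrized by mean m and dispersion d with
    variance m + d*m^2; dispersion 0 degenerates to deterministic counts
    round(m) (the documented all-ties behavior).
    Gene IDs are G00001.. ; planted_top_set must use those IDs.
    """
    import pandas as pd

    from cnvdriver.expression import ExpressionMatrix

    if nb_mean <= 0 or nb_dispersion < 0:
        raise ValueError("nb_mean must be > 0 and nb_dispersion >= 0")
    rng = stream_rng(seed, "expression")
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    unknown = set(planted_top_set) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted genes outside the gene ID space, e.g. {sorted(unknown)[:5]}")
    base = rng.uniform(0.5, 2.0, size=n_genes) * nb_mean
    planted = np.isin(gene_ids, list(planted_top_set))
    means = np.where(planted, 20.0 * nb_mean, base)

    cols, meta_rows = [], []
    data = np.empty((n_genes, len(strata) * samples_per_stratum), dtype=np.int64)
    j = 0
    for stage, region in strata:
        for si in range(samples_per_stratum):
            sid = f"{stage}_{region}_s{si + 1}"
            cols.append(sid)
            meta_rows.append((sid, stage, region))
            if nb_dispersion == 0:
                data[:, j] = np.round(means).astype(np.int64)
            else:
                n_param = 1.0 / nb_dispersion
                p_param = n_param / (n_param + means)
                data[:, j] = rng.negative_binomial(n_param, p_param)
            j += 1
    counts = pd.DataFrame(data, index=gene_ids, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "stage", "brain_region"]).set_index(
        "sample_id"
    )
    return ExpressionMatrix(counts, meta)


def generate_phenotypes(
    gene_carriers: Mapping[str, Sequence[str]],
    patients: Sequence[str],
    effects: Mapping[tuple[str, str], float],
    background: Mapping[str, float],
    seed: int = 0,
) -> PhenotypeTable:
    """Phenotype term lists with planted gene-phenotype incidences.

    A patient carrying an effect gene draws that gene's term at the effect
    incidence; everyone else draws each background term at its background
    incidence. A patient carrying several effect genes for the same term
    draws at the maximum applicable incidence.
    """
    for (g, t), inc in effects.items():
        if not (0.0 <= inc <= 1.0):
            raise ValueError(f"effect incidence {inc} for ({g}, {t}) outside [0, 1]")
    for t, inc in background.items():
        if not (0.0 <= inc <= 1.0):
            raise ValueError(f"background incidence {inc} for {t} outside [0, 1]")
    rng = stream_rng(seed, "phenotypes")
    carrier_of: dict[str, set[str]] = {}
    for g, pts in gene_carriers.items():
        for p in pts:
            carrier_of.setdefault(str(p), set()).add(g)
    terms = list(dict.fromkeys(list(background) + [t for (_, t) in effects]))
    table: dict[str, list[str]] = {}
    for pid in patients:
        drawn: list[str] = []
        genes = carrier_of.get(str(pid), set())
        for t in terms:
            inc = background.get(t, 0.0)
            for g in genes:
                inc = max(inc, effects.get((g, t), 0.0))
            if rng.random() < inc:
                drawn.append(t)
        table[str(pid)] = drawn
    return PhenotypeTable(table)


def default_locus_grid(n_loci: int, locus_length: int = 2_000_000, spacing: int = 12_000_000) -> list[Locus]:
    """Evenly spaced non-overlapping loci laid across the autosomes."""
    loci: list[Locus] = []
    chroms = list(GENOME_MB)
    ci, pos = 0, 10_000_000
    for i in range(n_loci):
        while pos + locus_length > GENOME_MB[chroms[ci]] * 1_000_000 - 1_000_000:
            ci = (ci + 1) % len(chroms)
            pos = 10_000_000
        chrom = chroms[ci]
        loci.append(Locus(f"L{i + 1:04d}", chrom, pos, pos + locus_length))
        pos += spacing
    return loci
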