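"""Core record types shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention). Chromosome
names are normalized by stripping a leading ``chr`` prefix, so ``chr1`` and
``1`` compare equal everywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

CNV_TYPES = ("DEL", "DUP")

CASE = "case"
CONTROL = "control"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; '23'/'X' style names pass through unchanged."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if not chrom:
        raise ValueError("empty chromosome name")
    return chrom


def _check_interval(start: int, end: int, what: str) -> None:
    if start < 0:
        raise ValueError(f"{what}: negative start {start}")
    if start >= end:
        raise ValueError(f"{what}: start {start} must be < end {end}")


@dataclass(frozen=True)
class CnvCall:
    """One copy-number event: a deletion or duplication carried by one sample."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    sample_id: str
    af: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        _check_interval(self.start, self.end, "CnvCall")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Locus:
    """A named genomic interval (cytoband-style) tested for CNV association."""

    locus_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        _check_interval(self.start, self.end, f"Locus {self.locus_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its CDS span plus dosage-sensitivity scores.

    pHI is the probability of haploinsufficiency (intolerance to one-copy
    loss), pTS the probability of triplosensitivity (intolerance to one-copy
    gain); both live in [0, 1].
    """

    gene_id: str
    chrom: str
    cds_start: int
    cds_end: int
    phi: float
    pts: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        _check_interval(self.cds_start, self.cds_end, f"GeneRecord {self.gene_id}")
        for name, score in (("pHI", self.phi), ("pTS", self.pts)):
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"{name} score {score} outside [0, 1] for {self.gene_id}")


class SampleTable:
    """Case/control labels per sample, with an optional cohort label."""

    def __init__(
        self,
        status: Mapping[str, str],
        cohort: Mapping[str, str] | None = None,
    ) -> None:
        self.status: dict[str, str] = {}
        for sid, lab in status.items():
            if lab not in (CASE, CONTROL):
                raise ValueError(f"sample {sid}: label {lab!r} is not 'case'/'control'")
            self.status[str(sid)] = lab
        self.cohort = dict(cohort) if cohort else {}

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.status

    def __len__(self) -> int:
        return len(self.status)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleTable)
            and self.status == other.status
            and self.cohort == other.cohort
        )

    @property
    def case_ids(self) -> list[str]:
        return [s for s, lab in self.status.items() if lab == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, lab in self.status.items() if lab == CONTROL]

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

# PLINK PED phenotype dialect
_PED_PHENO = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PED_PHENO_OUT = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}
PED_MISSING = "0"


@dataclass(frozen=True)
class PedigreeMember:
    family_id: str
    individual_id: str
    father_id: str  # PED_MISSING when absent
    mother_id: str
    sex: str  # "1" male, "2" female, "0" unknown
    affected: str  # affected / unaffected / unknown

    def __post_init__(self) -> None:
        if self.affected not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise ValueError(f"bad affection status {self.affected!r}")


class Pedigree:
    """Family structures linking parents to children for transmission counting."""

    def __init__(self, members: Iterable[PedigreeMember]) -> None:
        self.members = list(members)
        seen: set[tuple[str, str]] = set()
        for m in self.members:
            key = (m.family_id, m.individual_id)
            if key in seen:
                raise ValueError(
                    f"duplicate individual {m.individual_id!r} in family {m.family_id!r}"
                )
            seen.add(key)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            (m.family_id, m.individual_id): [p for p in (m.father_id, m.mother_id) if p != PED_MISSING]
            for m in self.members
        }
        for start in parents:
            fid = start[0]
            stack, seen = [start], set()
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                for p in parents.get(node, []):
                    anc = (fid, p)
                    if anc == start:
                        raise ValueError(f"individual {start[1]} is its own ancestor")
                    stack.append(anc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self.members == other.members

    def __len__(self) -> int:
        return len(self.members)

    def families(self) -> dict[str, list[PedigreeMember]]:
        fams: dict[str, list[PedigreeMember]] = {}
        for m in self.members:
            fams.setdefault(m.family_id, []).append(m)
        return fams


class GeneSetCatalog:
    """Named gene sets (GMT-like): set name -> list of gene IDs."""

    def __init__(self, sets: Mapping[str, Sequence[str]], descriptions: Mapping[str, str] | None = None) -> None:
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = [str(g) for g in genes]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[str(name)] = genes
        self.descriptions = dict(descriptions) if descriptions else {}

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCatalog) and self.sets == other.sets


class PhenotypeTable:
    """Flat phenotype term lists per patient (HPO-style term IDs, no hierarchy)."""

    def __init__(self, terms: Mapping[str, Sequence[str]]) -> None:
        self.terms: dict[str, list[str]] = {}
        for pid, tlist in terms.items():
            seen: list[str] = []
            for t in tlist:
                t = str(t)
                if t not in seen:
                    seen.append(t)
            self.terms[str(pid)] = seen

    @property
    def patients(self) -> list[str]:
        return list(self.terms)

    def has_term(self, patient_id: str, term: str) -> bool:
        return term in self.terms.get(patient_id, [])

    def all_terms(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for tlist in self.terms.values():
            for t in tlist:
                if t not in seen:
                    seen.add(t)
                    out.append(t)
        return out

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PhenotypeTable) and self.terms == other.terms


@dataclass(frozen=True)
class AssociationResult:
    """A 2x2 case-control (or set-overlap) test result.

    Counts follow the carrier layout: a = case carriers, b = case
    non-carriers, c = control carriers, d = control non-carriers. The odds
    ratio is the sample OR a*d/(b*c) (NaN when a carrier margin is empty;
    Haldane-Anscombe corrected when exactly one cell is zero).
    """

    unit_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    bonferroni_threshold: float
    significant: bool
    nominal: bool

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if v < 0:
                raise ValueError(f"count {name}={v} is negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def equals(self, other: "AssociationResult", rel: float = 0.0) -> bool:
        """Equality treating NaN odds ratios as equal (used by round-trip tests)."""
        same_or = (
            (math.isnan(self.odds_ratio) and math.isnan(other.odds_ratio))
            or self.odds_ratio == other.odds_ratio
        )
        return (
            self.unit_id == other.unit_id
            and (self.a, self.b, self.c, self.d) == (other.a, other.b, other.c, other.d)
            and same_or
            and self.p_value == other.p_value
            and self.bonferroni_threshold == other.bonferroni_threshold
            and self.significant == other.significant
            and self.nominal == other.nominal
        )


@dataclass(frozen=True)
class NoveltyCall:
    """Classification of a significant locus against known reference regions."""

    locus_id: str
    status: str  # known / novel / boundary_expansion
    matched_reference_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status not in ("known", "novel", "boundary_expansion"):
            raise ValueError(f"bad novelty status {self.status!r}")
        if self.status == "boundary_expansion" and not self.matched_reference_ids:
            raise ValueError("boundary_expansion requires at least one partial reference overlap")
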