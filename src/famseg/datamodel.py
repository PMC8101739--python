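"""Domain types shared across the pipeline.

Genotypes are unphased alternate-allele dosages. A dosage is one of
``{0, 1, 2}`` or :data:`MISSING` (-1); no fractional values are allowed.
Coordinates follow the VCF convention: 1-based positions, indels anchored
on the preceding reference base, and multi-allelic records split into one
:class:`VariantKey` per alternate allele before any filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_VALID_DOSAGES = frozenset({0, 1, 2, MISSING})
_ALLELE_CHARS = frozenset("ACGT")

#: Reserved family id for independent (family-less) controls.
CONTROL_FAMILY_ID = "CTRL"

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass(frozen=True, order=True)
class VariantKey:
    """One normalized biallelic variant: (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"{name} must be a non-empty ACGT string, got {allele!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse a ``chrom:pos:ref:alt`` label."""
        parts = text.split(":")
        if len(parts) != 4:
            raise ValueError(f"expected chrom:pos:ref:alt, got {text!r}")
        return cls(parts[0], int(parts[1]), parts[2].upper(), parts[3].upper())


def validate_dosage(d: int) -> int:
    if d not in _VALID_DOSAGES:
        raise ValueError(f"dosage must be 0, 1, 2 or MISSING ({MISSING}), got {d}")
    return d


@dataclass
class GenotypeMatrix:
    """Rectangular dosage matrix over (variants x samples).

    ``dosages[i, j]`` is the alternate-allele dosage of ``samples[j]`` at
    ``variants[i]``; -1 encodes a missing call.
    """

    variants: list[VariantKey]
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample IDs must be unique")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant keys must be unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]} at ({self.variants[i]}, {self.samples[j]})"
            )
        self._vindex = {v: i for i, v in enumerate(self.variants)}
        self._sindex = {s: j for j, s in enumerate(self.samples)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_index(self, key: VariantKey) -> int:
        return self._vindex[key]

    def sample_index(self, sample_id: str) -> int:
        return self._sindex[sample_id]

    def has_variant(self, key: VariantKey) -> bool:
        return key in self._vindex

    def dosage(self, key: VariantKey, sample_id: str) -> int:
        return int(self.dosages[self._vindex[key], self._sindex[sample_id]])

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Dosage sub-matrix for the given samples (variants x len(ids))."""
        idx = [self._sindex[s] for s in sample_ids]
        return self.dosages[:, idx]

    def carriers(self, key: VariantKey) -> list[str]:
        """Sample IDs with dosage >= 1 at *key*."""
        row = self.dosages[self._vindex[key]]
        return [s for s, d in zip(self.samples, row) if d >= 1]


@dataclass
class Sample:
    """One pedigree member with phenotype and study-role metadata."""

    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"  # female | male | unknown
    affection: str = "unknown"  # affected | unaffected | unknown
    is_proband: bool = False
    is_independent_control: bool = False
    onset_age: Optional[float] = None
    current_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.affection not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"invalid affection {self.affection!r}")
        if self.onset_age is not None and self.affection != "affected":
            raise ValueError(
                f"onset_age set on non-affected sample {self.sample_id!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class PedigreeSet:
    """Families with affection status, proband flags and case/control labels.

    ``case_status`` maps family_id to ``"BPPV"`` (case family) or
    ``"non-BPPV"`` (control family / independent-control pool).
    """

    families: dict[str, list[Sample]]
    case_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.case_status:
            self.case_status = {
                fid: ("BPPV" if any(m.affection == "affected" for m in members)
                      and fid != CONTROL_FAMILY_ID else "non-BPPV")
                for fid, members in self.families.items()
            }
        for fid, members in self.families.items():
            ids = [m.sample_id for m in members]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate sample IDs within family {fid}")
            probands = [m for m in members if m.is_proband]
            if len(probands) > 1:
                raise ValueError(f"family {fid} has {len(probands)} probands")
            known = set(ids)
            for m in members:
                for pid in (m.father_id, m.mother_id):
                    if pid is not None and pid not in known:
                        raise ValueError(
                            f"parent {pid!r} of {m.sample_id!r} not found in family {fid}"
                        )
            if self.case_status.get(fid) == "BPPV" and not any(
                m.affection == "affected" for m in members
            ):
                raise ValueError(f"BPPV family {fid} has no affected member")

    def __iter__(self) -> Iterator[tuple[str, list[Sample]]]:
        return iter(self.families.items())

    def all_samples(self) -> list[Sample]:
        return [m for members in self.families.values() for m in members]

    def sample(self, sample_id: str) -> Sample:
        for m in self.all_samples():
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def case_family_ids(self) -> list[str]:
        return [f for f, s in self.case_status.items() if s == "BPPV"]

    def control_family_ids(self) -> list[str]:
        """Non-BPPV control families, excluding the independent-control pool."""
        return [
            f for f, s in self.case_status.items()
            if s == "non-BPPV" and f != CONTROL_FAMILY_ID
            and not any(m.is_independent_control for m in self.families[f])
        ]

    def independent_controls(self) -> list[Sample]:
        return [m for m in self.all_samples() if m.is_independent_control]

    def unaffected_samples(self) -> list[Sample]:
        """Every unaffected individual cohort-wide, controls included."""
        return [m for m in self.all_samples() if m.affection == "unaffected"]

    def proband(self, family_id: str) -> Optional[Sample]:
        """Designated proband, with a fixed fallback order.

        Explicit flag, else the earliest-onset affected member, else the
        lexicographically first affected member; for families without any
        affected member (control families), the lexicographically first
        member.
        """
        members = self.families[family_id]
        for m in members:
            if m.is_proband:
                return m
        affected = [m for m in members if m.affection == "affected"]
        if affected:
            with_onset = [m for m in affected if m.onset_age is not None]
            if with_onset:
                return min(with_onset, key=lambda m: (m.onset_age, m.sample_id))
            return min(affected, key=lambda m: m.sample_id)
        if members:
            return min(members, key=lambda m: m.sample_id)
        return None


@dataclass
class VariantAnnotation:
    """Per-variant functional annotation (gene, impact class, MAF, CADD)."""

    key: VariantKey
    gene: Optional[str] = None
    impact: Optional[str] = None  # HIGH | MODERATE | LOW | MODIFIER
    maf: Optional[float] = None
    cadd: Optional[float] = None
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.impact is not None and self.impact not in IMPACT_CLASSES:
            raise ValueError(f"invalid impact class {self.impact!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"MAF out of [0,1]: {self.maf}")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"negative CADD score: {self.cadd}")


def annotation_index(
    annotations: Iterable[VariantAnnotation],
) -> dict[VariantKey, VariantAnnotation]:
    return {a.key: a for a in annotations}


@dataclass
class GeneSet:
    """A named set of gene symbols; symbols are uppercased on load."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.genes = frozenset(g.upper() for g in self.genes)

    def __contains__(self, gene: Optional[str]) -> bool:
        return gene is not None and gene.upper() in self.genes


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-positive/negative counts for cases (a, b) vs controls (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(not isinstance(x, (int, np.integer)) for x in cells):
            raise TypeError("contingency counts must be integers")
        if any(x < 0 for x in cells):
            raise ValueError(f"negative count in table {cells}")
        if sum(cells) == 0:
            raise ValueError("contingency table has zero grand total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)
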