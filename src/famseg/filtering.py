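"""Tiered variant selection for multiplex families under a dominant model.

The funnel has four tiers:

1. drop low-impact annotation classes (LOW, MODIFIER by default);
2. per-family segregation — keep variants shared in identical zygosity by
   every affected member of a family and absent (dosage 0) from its
   unaffected members;
3. rarity/deleteriousness — keep variants with MAF below threshold OR
   CADD above threshold;
4. cross-family exclusion — drop any candidate carried by an unaffected
   individual or independent control anywhere in the cohort — followed by
   prioritization flags (shared by >=2 families, inner-ear expression,
   balance/hearing gene).

The design target is an autosomal-dominant trait with reduced penetrance
and genetic heterogeneity across families, so each family is first
evaluated on its own and only then compared against the full cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .datamodel import (
    MISSING,
    GeneSet,
    GenotypeMatrix,
    PedigreeSet,
    Sample,
    VariantAnnotation,
    VariantKey,
    annotation_index,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds and policies for the tiered filter.

    maf_threshold / cadd_threshold implement the "MAF < 0.05 OR CADD > 9"
    rarity rule; neither is stringent, by design, to limit false negatives
    at the screening stage. ``zygosity_strict`` requires all affected
    members of a family to share the identical zygosity state (het or hom),
    not merely carrier status. ``missing_policy`` decides what a missing
    call inside a family does to a candidate.
    """

    maf_threshold: float = 0.05
    cadd_threshold: float = 9.0
    dropped_impacts: frozenset[str] = frozenset({"LOW", "MODIFIER"})
    min_sharing_families: int = 2
    zygosity_strict: bool = True
    missing_policy: str = "exclude_variant"  # or "treat_as_noncarrier"
    exclude_on_affected_noncarrier: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValueError(f"maf_threshold out of (0,1): {self.maf_threshold}")
        if self.cadd_threshold < 0:
            raise ValueError(f"negative cadd_threshold: {self.cadd_threshold}")
        if self.missing_policy not in ("exclude_variant", "treat_as_noncarrier"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        self.dropped_impacts = frozenset(self.dropped_impacts)


class SharedState(NamedTuple):
    """A candidate variant with the zygosity shared by a family's affecteds."""

    key: VariantKey
    state: str  # "het" | "hom"


class PrioritizedVariant(NamedTuple):
    key: VariantKey
    flags: dict
    rank: int


@dataclass
class TierReport:
    """Surviving variants and counts at each tier of the funnel."""

    per_family_candidates: dict[str, set[SharedState]]
    after_freq_impact: dict[str, set[SharedState]]
    after_cross_family: set[VariantKey]
    prioritized: list[PrioritizedVariant]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            union2 = {s.key for ss in self.per_family_candidates.values() for s in ss}
            union3 = {s.key for ss in self.after_freq_impact.values() for s in ss}
            self.counts = {
                "segregating_union": len(union2),
                "freq_impact_union": len(union3),
                "cross_family": len(self.after_cross_family),
                "prioritized": len(self.prioritized),
            }


def impact_prefilter(
    annotations: Iterable[VariantAnnotation], config: FilterConfig
) -> set[VariantKey]:
    """Keys whose impact class is not dropped; unannotated impact is retained."""
    return {
        a.key
        for a in annotations
        if a.impact is None or a.impact not in config.dropped_impacts
    }


def family_segregation(
    family: Sequence[Sample],
    matrix: GenotypeMatrix,
    config: FilterConfig,
    extra_unaffected: Sequence[Sample] = (),
    restrict_to: Optional[set[VariantKey]] = None,
) -> set[SharedState]:
    """Variants shared by all affected members and absent from unaffecteds.

    A variant qualifies with state ``het``/``hom`` when every affected
    member carries that identical dosage (1 or 2) and every unaffected
    member (including any borrowed independent controls in
    *extra_unaffected*) has dosage 0. With ``zygosity_strict=False`` any
    affected dosage >= 1 qualifies and the state is recorded as ``het``.
    Missing calls follow ``config.missing_policy``.
    """
    members = list(family) + list(extra_unaffected)
    affected = [m.sample_id for m in family if m.affection == "affected"]
    affected = [s for s in affected if s in matrix.samples]
    if not affected:
        raise ValueError(
            f"family {family[0].family_id if family else '?'}: "
            "no affected genotyped members"
        )
    unaffected = [
        m.sample_id
        for m in members
        if m.affection == "unaffected" and m.sample_id in matrix.samples
    ]
    aff = matrix.sample_columns(affected)  # (V, n_aff)
    una = (
        matrix.sample_columns(unaffected)
        if unaffected
        else np.empty((matrix.n_variants, 0), dtype=np.int8)
    )
    any_missing = (aff == MISSING).any(axis=1) | (una == MISSING).any(axis=1)
    if config.missing_policy == "treat_as_noncarrier":
        aff = np.where(aff == MISSING, 0, aff)
        una = np.where(una == MISSING, 0, una)
        any_missing = np.zeros(matrix.n_variants, dtype=bool)
    unaffected_clear = (una == 0).all(axis=1)
    out: set[SharedState] = set()
    if config.zygosity_strict:
        all_het = (aff == 1).all(axis=1)
        all_hom = (aff == 2).all(axis=1)
        keep_het = all_het & unaffected_clear & ~any_missing
        keep_hom = all_hom & unaffected_clear & ~any_missing
        for i in np.flatnonzero(keep_het):
            out.add(SharedState(matrix.variants[i], "het"))
        for i in np.flatnonzero(keep_hom):
            out.add(SharedState(matrix.variants[i], "hom"))
    else:
        all_carrier = (aff >= 1).all(axis=1)
        keep = all_carrier & unaffected_clear & ~any_missing
        for i in np.flatnonzero(keep):
            out.add(SharedState(matrix.variants[i], "het"))
    if restrict_to is not None:
        out = {s for s in out if s.key in restrict_to}
    return out


def freq_impact_filter(
    candidates: set[SharedState],
    annotations: Iterable[VariantAnnotation],
    config: FilterConfig,
) -> set[SharedState]:
    """Keep candidates with MAF < threshold OR CADD > threshold.

    A variant with no recorded MAF is treated as rare (novel allele) and
    passes the MAF clause; an absent CADD score fails the CADD clause.
    """
    ann = annotation_index(annotations)
    out: set[SharedState] = set()
    for cand in candidates:
        a = ann.get(cand.key)
        maf = a.maf if a is not None else None
        cadd = a.cadd if a is not None else None
        maf_pass = maf is None or maf < config.maf_threshold
        cadd_pass = cadd is not None and cadd > config.cadd_threshold
        if maf_pass or cadd_pass:
            out.add(cand)
    return out


def cross_family_exclusion(
    per_family: Mapping[str, set[SharedState]],
    pedigrees: PedigreeSet,
    matrix: GenotypeMatrix,
    config: Optional[FilterConfig] = None,
) -> set[VariantKey]:
    """Drop candidates contradicted elsewhere in the cohort.

    A candidate is excluded when any unaffected subject in ANY family —
    or any independent control — carries it (dosage >= 1). With
    ``exclude_on_affected_noncarrier=True`` a stricter reading also drops
    candidates absent from an affected member of another candidate family.
    """
    config = config or FilterConfig()
    candidate_keys = {s.key for states in per_family.values() for s in states}
    if not candidate_keys:
        return set()
    unaffected_ids = [
        m.sample_id
        for m in pedigrees.unaffected_samples()
        if m.sample_id in matrix.samples
    ]
    excluded: set[VariantKey] = set()
    if unaffected_ids:
        una = matrix.sample_columns(unaffected_ids)
        carried = (una >= 1).any(axis=1)
        for i in np.flatnonzero(carried):
            excluded.add(matrix.variants[i])
    if config.exclude_on_affected_noncarrier:
        key_families: dict[VariantKey, set[str]] = {}
        for fid, states in per_family.items():
            for s in states:
                key_families.setdefault(s.key, set()).add(fid)
        for key in candidate_keys:
            vi = matrix.variant_index(key)
            for fid in pedigrees.case_family_ids():
                if fid in key_families.get(key, set()):
                    continue
                aff_ids = [
                    m.sample_id
                    for m in pedigrees.families[fid]
                    if m.affection == "affected" and m.sample_id in matrix.samples
                ]
                if not aff_ids:
                    continue
                dos = matrix.dosages[vi, [matrix.sample_index(s) for s in aff_ids]]
                if (dos == 0).any():
                    excluded.add(key)
                    break
    survivors = candidate_keys - excluded
    for key in sorted(excluded & candidate_keys):
        logger.debug("cross-family exclusion removed %s", key)
    return survivors


def prioritize(
    survivors: set[VariantKey],
    per_family: Mapping[str, set[SharedState]],
    inner_ear: GeneSet,
    balance: GeneSet,
    annotations: Iterable[VariantAnnotation],
    config: FilterConfig,
) -> list[PrioritizedVariant]:
    """Flag and rank surviving candidates for follow-up.

    Flags: ``multi_family`` (shared by >= min_sharing_families families),
    ``inner_ear`` (gene in the inner-ear expression set), ``balance``
    (gene in the balance/hearing set). Variants with at least one flag are
    prioritized; ordering is flag count desc, then number of sharing
    families desc, then CADD desc, then (chrom, pos) asc — a deterministic
    total order.
    """
    ann = annotation_index(annotations)
    key_families: dict[VariantKey, set[str]] = {}
    for fid, states in per_family.items():
        for s in states:
            key_families.setdefault(s.key, set()).add(fid)
    entries = []
    for key in survivors:
        a = ann.get(key)
        gene = a.gene if a is not None else None
        n_fam = len(key_families.get(key, set()))
        flags = {
            "multi_family": n_fam >= config.min_sharing_families,
            "inner_ear": gene in inner_ear,
            "balance": gene in balance,
        }
        if not any(flags.values()):
            continue
        cadd = a.cadd if a is not None and a.cadd is not None else -1.0
        entries.append((key, flags, sum(flags.values()), n_fam, cadd))
    entries.sort(key=lambda e: (-e[2], -e[3], -e[4], e[0]))
    return [
        PrioritizedVariant(key=key, flags=flags, rank=rank)
        for rank, (key, flags, *_ignored) in enumerate(entries, start=1)
    ]


def run_tiered_pipeline(
    matrix: GenotypeMatrix,
    annotations: Iterable[VariantAnnotation],
    pedigrees: PedigreeSet,
    inner_ear: GeneSet,
    balance: GeneSet,
    config: Optional[FilterConfig] = None,
) -> TierReport:
    """Execute the full funnel on a cohort and record tier counts.

    Case families without their own unaffected members borrow the cohort's
    designated independent controls as unaffecteds during segregation.
    Every PED sample must be genotyped; missing IDs are an error.
    """
    config = config or FilterConfig()
    annotations = list(annotations)
    missing_ids = [
        m.sample_id
        for m in pedigrees.all_samples()
        if m.sample_id not in matrix.samples
    ]
    if missing_ids:
        raise ValueError(f"PED samples missing from genotype matrix: {missing_ids}")
    impact_pass = impact_prefilter(annotations, config)
    controls = pedigrees.independent_controls()
    per_family: dict[str, set[SharedState]] = {}
    for fid in pedigrees.case_family_ids():
        members = pedigrees.families[fid]
        has_unaffected = any(m.affection == "unaffected" for m in members)
        extra = () if has_unaffected else controls
        per_family[fid] = family_segregation(
            members, matrix, config, extra_unaffected=extra, restrict_to=impact_pass
        )
    after_freq: dict[str, set[SharedState]] = {
        fid: freq_impact_filter(states, annotations, config)
        for fid, states in per_family.items()
    }
    survivors = cross_family_exclusion(after_freq, pedigrees, matrix, config)
    prioritized = prioritize(
        survivors, after_freq, inner_ear, balance, annotations, config
    )
    report = TierReport(
        per_family_candidates=per_family,
        after_freq_impact=after_freq,
        after_cross_family=survivors,
        prioritized=prioritized,
    )
    report.counts["impact_pass"] = len(impact_pass)
    for fid in sorted(per_family):
        logger.info(
            "family %s: %d segregating, %d after MAF/CADD",
            fid,
            len(per_family[fid]),
            len(after_freq[fid]),
        )
    logger.info(
        "funnel: %d segregating -> %d after MAF/CADD -> %d after cross-family -> %d prioritized",
        report.counts["segregating_union"],
        report.counts["freq_impact_union"],
        report.counts["cross_family"],
        report.counts["prioritized"],
    )
    return report
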