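"""Synthetic multiplex-family exome cohorts for a dominant trait.

The generator emulates the statistical structure the tiered analysis
assumes: case families ascertained for multiple affected relatives and
segregating a rare autosomal-dominant risk variant with reduced
penetrance, non-BPPV control families ascertained for the absence of the
phenotype, a pool of independent elderly controls, and a background of
unlinked exonic variants with a rare-skewed frequency spectrum.

Generative model, per seeded run:

* background variant frequencies come from a 70/30 mixture of
  Beta(0.2, 8) (rare-skewed) and Uniform(0.05, 0.5) (common); founders
  are drawn in Hardy-Weinberg proportions and non-founders by Mendelian
  gene-drop (each parent transmits the alternate allele with probability
  dosage/2, sites unlinked);
* the causal variant is planted heterozygous in one founder of every
  designated case family and drawn at its population frequency in
  control families and independent controls;
* affection is penetrant carriage OR phenocopy; onset ages for affected
  samples are Normal draws whose means differ by carrier status;
* ascertainment mirrors the study design by rejection sampling — case
  families are redrawn until they contain at least ``ascertain_min_affected``
  affected members (and enough members to sequence), control families and
  independent controls until no member is affected.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import (
    CONTROL_FAMILY_ID,
    MISSING,
    GeneSet,
    GenotypeMatrix,
    PedigreeSet,
    Sample,
    VariantAnnotation,
    VariantKey,
)
from .io import write_candidates, write_ped, write_vcf

#: Default sequencing templates for the 12 case families:
#: (affected members sequenced, unaffected members sequenced) per family,
#: summing to 28 affected and 7 unaffected relatives across the cohort.
DEFAULT_FAMILY_TEMPLATES: tuple[tuple[int, int], ...] = (
    (3, 1), (2, 0), (2, 1), (3, 0), (2, 1), (2, 1),
    (3, 0), (2, 1), (2, 0), (3, 1), (2, 0), (2, 1),
)

CAUSAL_KEY = VariantKey("chr5", 140873105, "A", "AA")
CAUSAL_GENE = "PCDHGA10"
CAUSAL_RSID = "rs113784532"


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed is mandatory.

    Defaults encode the emulated study conditions: 12 case families with
    2-3 affected and 0-2 unaffected sequenced members each, 50 non-BPPV
    control families, 7 independent controls, penetrance 0.95, a 2%
    phenocopy rate, onset ages of 44.0 +/- 14.0 years for carriers versus
    54.4 +/- 16.1 for non-carriers, and a 2.1:1 female/male ratio.
    """

    seed: int
    n_case_families: int = 12
    n_control_families: int = 50
    n_independent_controls: int = 7
    family_templates: tuple[tuple[int, int], ...] = DEFAULT_FAMILY_TEMPLATES
    n_background_variants: int = 5000
    rare_fraction: float = 0.70
    rare_beta: tuple[float, float] = (0.2, 8.0)
    common_uniform: tuple[float, float] = (0.05, 0.5)
    cadd_uniform: tuple[float, float] = (0.0, 40.0)
    impact_probs: tuple[float, float, float, float] = (0.03, 0.25, 0.30, 0.42)
    causal_maf: float = 0.005
    penetrance: float = 0.95
    phenocopy_rate: float = 0.02
    onset_carrier: tuple[float, float] = (44.0, 14.0)
    onset_noncarrier: tuple[float, float] = (54.4, 16.1)
    female_fraction: float = 0.68
    genotype_missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    ascertain_min_affected: int = 2
    inner_ear_fraction: float = 0.08
    balance_fraction: float = 0.05
    max_resample: int = 10_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = (
            self.causal_maf, self.penetrance, self.phenocopy_rate,
            self.female_fraction, self.genotype_missing_rate,
            self.genotype_error_rate, self.rare_fraction,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if self.penetrance < self.phenocopy_rate:
            raise ValueError("penetrance must be >= phenocopy_rate")
        if abs(sum(self.impact_probs) - 1.0) > 1e-9:
            raise ValueError("impact_probs must sum to 1")
        if self.causal_maf >= 0.05:
            warnings.warn(
                "causal_maf >= 0.05: the planted variant would fail the "
                "default rarity filter",
                stacklevel=2,
            )


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort, for recovery tests."""

    causal_key: VariantKey
    carrier_samples: set[str]
    carrier_families: set[str]
    provenance: dict[str, str]  # sample -> penetrant_carrier | nonpenetrant_carrier
    #                                      | phenocopy | noncarrier_unaffected


@dataclass
class Cohort:
    """A simulated cohort: sequenced matrix + pedigree + annotations + truth.

    ``full_matrix`` / ``full_pedigrees`` additionally include unsequenced
    family members (with intact parent links) so Mendelian transmission
    can be audited; the sequenced views are what the analysis consumes.
    """

    matrix: GenotypeMatrix
    pedigrees: PedigreeSet
    annotations: list[VariantAnnotation]
    truth: TruthRecord
    inner_ear: GeneSet
    balance: GeneSet
    config: SimulationConfig
    full_matrix: GenotypeMatrix
    full_pedigrees: PedigreeSet


def _draw_mafs(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    n = config.n_background_variants
    is_rare = rng.random(n) < config.rare_fraction
    a, b = config.rare_beta
    lo, hi = config.common_uniform
    mafs = np.where(
        is_rare,
        rng.beta(a, b, size=n),
        rng.uniform(lo, hi, size=n),
    )
    return np.clip(mafs, 1e-4, 0.5)


def _transmit(rng: np.random.Generator, parent_dosage: np.ndarray) -> np.ndarray:
    """One gamete per unlinked site: alt allele with probability dosage/2."""
    return (rng.random(parent_dosage.shape) < parent_dosage / 2.0).astype(np.int8)


def gene_drop_child(
    rng: np.random.Generator, father: np.ndarray, mother: np.ndarray
) -> np.ndarray:
    """Mendelian offspring dosages from two parental dosage vectors."""
    return _transmit(rng, np.asarray(father)) + _transmit(rng, np.asarray(mother))


def _affection(
    rng: np.random.Generator, carrier: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    u = rng.random(carrier.shape)
    return np.where(carrier, u < config.penetrance, u < config.phenocopy_rate)


def _sex(rng: np.random.Generator, config: SimulationConfig) -> str:
    return "female" if rng.random() < config.female_fraction else "male"


def _onset(rng: np.random.Generator, carrier: bool, config: SimulationConfig) -> float:
    mean, sd = config.onset_carrier if carrier else config.onset_noncarrier
    return float(rng.normal(mean, sd))


class _FamilyDraw:
    """One realized family: member metadata plus per-member dosage vectors."""

    def __init__(self) -> None:
        self.samples: list[Sample] = []
        self.dosages: dict[str, np.ndarray] = {}  # sample_id -> (V+1,) incl. causal row
        self.sequenced: list[str] = []


def _draw_case_family(
    rng: np.random.Generator,
    fid: str,
    template: tuple[int, int],
    mafs: np.ndarray,
    config: SimulationConfig,
) -> _FamilyDraw:
    n_aff_seq, n_unaff_seq = template
    n_children = n_aff_seq + n_unaff_seq + 1
    v = len(mafs)
    for _ in range(config.max_resample):
        # founders: HWE background; father carries the planted causal het
        father_bg = rng.binomial(2, mafs).astype(np.int8)
        mother_bg = rng.binomial(2, mafs).astype(np.int8)
        father = np.concatenate([father_bg, np.int8([1])])
        mother = np.concatenate([mother_bg, np.int8([0])])
        children = [
            _transmit(rng, father) + _transmit(rng, mother)
            for _ in range(n_children)
        ]
        genos = [father, mother] + children
        carrier = np.array([g[-1] >= 1 for g in genos])
        affected = _affection(rng, carrier, config)
        need_aff = max(config.ascertain_min_affected, n_aff_seq)
        if config.ascertain_min_affected > 0:
            if affected.sum() < need_aff or (~affected).sum() < n_unaff_seq:
                continue
        draw = _FamilyDraw()
        ids = [f"{fid}_F", f"{fid}_M"] + [f"{fid}_C{k+1}" for k in range(n_children)]
        parent_of = {ids[0]: (None, None), ids[1]: (None, None)}
        for cid in ids[2:]:
            parent_of[cid] = (ids[0], ids[1])
        for idx, sid in enumerate(ids):
            is_aff = bool(affected[idx])
            sex = "male" if idx == 0 else "female" if idx == 1 else _sex(rng, config)
            onset = _onset(rng, bool(carrier[idx]), config) if is_aff else None
            current = (
                (onset if onset is not None else 0.0) + float(rng.uniform(0, 15))
                if is_aff
                else float(rng.uniform(55, 85))
            )
            draw.samples.append(
                Sample(
                    sample_id=sid,
                    family_id=fid,
                    father_id=parent_of[sid][0],
                    mother_id=parent_of[sid][1],
                    sex=sex,
                    affection="affected" if is_aff else "unaffected",
                    onset_age=onset,
                    current_age=round(current, 1),
                )
            )
            draw.dosages[sid] = genos[idx]
        aff_ids = [s.sample_id for s in draw.samples if s.affection == "affected"]
        unaff_ids = [s.sample_id for s in draw.samples if s.affection == "unaffected"]
        draw.sequenced = aff_ids[:n_aff_seq] + unaff_ids[:n_unaff_seq]
        # proband: sequenced affected member with the earliest onset
        seq_aff = [s for s in draw.samples if s.sample_id in draw.sequenced
                   and s.affection == "affected"]
        if seq_aff:
            proband = min(seq_aff, key=lambda s: (s.onset_age or 0.0, s.sample_id))
            proband.is_proband = True
        return draw
    raise RuntimeError(f"could not ascertain case family {fid} in {config.max_resample} draws")


def _draw_unaffected_individual(
    rng: np.random.Generator,
    mafs: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, bool]:
    """One founder genotype vector (background + causal), rejected if affected."""
    for _ in range(config.max_resample):
        bg = rng.binomial(2, mafs).astype(np.int8)
        causal = np.int8(rng.binomial(2, config.causal_maf))
        geno = np.concatenate([bg, [causal]])
        carrier = bool(geno[-1] >= 1)
        u = float(rng.random())
        affected = u < (config.penetrance if carrier else config.phenocopy_rate)
        if config.ascertain_min_affected > 0 and affected:
            continue
        return geno, affected
    raise RuntimeError("could not draw an unaffected control individual")


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one cohort under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    v = config.n_background_variants
    mafs = _draw_mafs(rng, config)
    positions = np.sort(
        rng.choice(np.arange(1_000, 99_000_000, 17), size=v, replace=False)
    )
    # avoid colliding with the fixed causal coordinate
    positions = np.where(positions == CAUSAL_KEY.pos, positions + 1, positions)
    cadd = rng.uniform(*config.cadd_uniform, size=v)
    impacts = rng.choice(
        ["HIGH", "MODERATE", "LOW", "MODIFIER"], size=v, p=config.impact_probs
    )
    keys = [
        VariantKey("chr5", int(pos), "A", "G") for pos in positions
    ] + [CAUSAL_KEY]
    genes = [f"GENE{i:05d}" for i in range(v)]
    annotations = [
        VariantAnnotation(
            key=keys[i],
            gene=genes[i],
            impact=str(impacts[i]),
            maf=float(mafs[i]),
            cadd=float(cadd[i]),
        )
        for i in range(v)
    ]
    annotations.append(
        VariantAnnotation(
            key=CAUSAL_KEY,
            gene=CAUSAL_GENE,
            impact="HIGH",
            maf=config.causal_maf,
            cadd=25.0,
            rsid=CAUSAL_RSID,
        )
    )
    # gene sets: a slice of background genes plus the causal gene
    n_inner = max(1, int(config.inner_ear_fraction * v))
    n_balance = max(1, int(config.balance_fraction * v))
    inner_genes = set(rng.choice(genes, size=n_inner, replace=False)) | {CAUSAL_GENE}
    balance_genes = set(rng.choice(genes, size=n_balance, replace=False)) | {CAUSAL_GENE}
    inner_ear = GeneSet(name="inner_ear", genes=frozenset(inner_genes))
    balance = GeneSet(name="balance", genes=frozenset(balance_genes))

    all_samples: list[Sample] = []
    all_dosages: dict[str, np.ndarray] = {}
    sequenced: list[str] = []

    templates = config.family_templates
    for i in range(config.n_case_families):
        fid = f"FB{i+1:03d}"
        template = templates[i % len(templates)]
        draw = _draw_case_family(rng, fid, template, mafs, config)
        all_samples.extend(draw.samples)
        all_dosages.update(draw.dosages)
        sequenced.extend(draw.sequenced)

    for i in range(config.n_control_families):
        fid = f"NB{i+1:03d}"
        for j, suffix in enumerate(("A", "B")):
            sid = f"{fid}_{suffix}"
            geno, _ = _draw_unaffected_individual(rng, mafs, config)
            all_dosages[sid] = geno
            all_samples.append(
                Sample(
                    sample_id=sid,
                    family_id=fid,
                    sex=_sex(rng, config),
                    affection="unaffected",
                    current_age=round(float(rng.uniform(55, 85)), 1),
                )
            )
            sequenced.append(sid)

    for i in range(config.n_independent_controls):
        sid = f"{CONTROL_FAMILY_ID}_{i+1:02d}"
        geno, _ = _draw_unaffected_individual(rng, mafs, config)
        all_dosages[sid] = geno
        all_samples.append(
            Sample(
                sample_id=sid,
                family_id=CONTROL_FAMILY_ID,
                sex=_sex(rng, config),
                affection="unaffected",
                is_independent_control=True,
                current_age=round(float(rng.uniform(55, 85)), 1),
            )
        )
        sequenced.append(sid)

    full_order = [s.sample_id for s in all_samples]
    full_dosages = np.column_stack([all_dosages[s] for s in full_order]).astype(np.int8)
    full_matrix = GenotypeMatrix(variants=list(keys), samples=full_order, dosages=full_dosages)
    full_families: dict[str, list[Sample]] = {}
    for s in all_samples:
        full_families.setdefault(s.family_id, []).append(s)
    full_pedigrees = PedigreeSet(families=full_families)

    # sequenced views: drop unsequenced members and orphan the parent links
    seq_set = set(sequenced)
    seq_families: dict[str, list[Sample]] = {}
    for s in all_samples:
        if s.sample_id not in seq_set:
            continue
        clone = Sample(
            sample_id=s.sample_id,
            family_id=s.family_id,
            father_id=s.father_id if s.father_id in seq_set else None,
            mother_id=s.mother_id if s.mother_id in seq_set else None,
            sex=s.sex,
            affection=s.affection,
            is_proband=s.is_proband,
            is_independent_control=s.is_independent_control,
            onset_age=s.onset_age,
            current_age=s.current_age,
        )
        seq_families.setdefault(s.family_id, []).append(clone)
    seq_dosages = np.column_stack([all_dosages[s] for s in sequenced]).astype(np.int8)
    if config.genotype_error_rate > 0:
        err = rng.random(seq_dosages.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=seq_dosages.shape).astype(np.int8)
        seq_dosages = np.where(err, (seq_dosages + shift) % 3, seq_dosages).astype(np.int8)
    if config.genotype_missing_rate > 0:
        miss = rng.random(seq_dosages.shape) < config.genotype_missing_rate
        seq_dosages = np.where(miss, np.int8(MISSING), seq_dosages).astype(np.int8)
    matrix = GenotypeMatrix(variants=list(keys), samples=list(sequenced), dosages=seq_dosages)
    pedigrees = PedigreeSet(families=seq_families)

    causal_row = full_matrix.dosages[full_matrix.variant_index(CAUSAL_KEY)]
    provenance: dict[str, str] = {}
    for s in all_samples:
        dose = int(causal_row[full_matrix.sample_index(s.sample_id)])
        carrier = dose >= 1
        if carrier and s.affection == "affected":
            provenance[s.sample_id] = "penetrant_carrier"
        elif carrier:
            provenance[s.sample_id] = "nonpenetrant_carrier"
        elif s.affection == "affected":
            provenance[s.sample_id] = "phenocopy"
        else:
            provenance[s.sample_id] = "noncarrier_unaffected"
    carrier_samples = {s for s in sequenced if matrix.dosage(CAUSAL_KEY, s) >= 1}
    carrier_families = {
        m.family_id for m in pedigrees.all_samples() if m.sample_id in carrier_samples
    }
    truth = TruthRecord(
        causal_key=CAUSAL_KEY,
        carrier_samples=carrier_samples,
        carrier_families=carrier_families,
        provenance=provenance,
    )
    return Cohort(
        matrix=matrix,
        pedigrees=pedigrees,
        annotations=annotations,
        truth=truth,
        inner_ear=inner_ear,
        balance=balance,
        config=config,
        full_matrix=full_matrix,
        full_pedigrees=full_pedigrees,
    )


def plant_contradiction(cohort: Cohort, target_sample_id: str) -> Cohort:
    """Make one unaffected sample a causal-variant carrier (in place).

    Models the observed unaffected carrier in a control family; the truth
    record is updated. Raises if the target is affected or unknown.
    """
    sample = cohort.pedigrees.sample(target_sample_id)  # KeyError if absent
    if sample.affection != "unaffected":
        raise ValueError(f"target {target_sample_id!r} is not unaffected")
    for mat in (cohort.matrix, cohort.full_matrix):
        if target_sample_id in mat.samples:
            mat.dosages[
                mat.variant_index(cohort.truth.causal_key),
                mat.sample_index(target_sample_id),
            ] = 1
    cohort.truth.carrier_samples.add(target_sample_id)
    cohort.truth.carrier_families.add(sample.family_id)
    cohort.truth.provenance[target_sample_id] = "nonpenetrant_carrier"
    return cohort


def mendelian_violations(matrix: GenotypeMatrix, pedigrees: PedigreeSet) -> int:
    """Count (child, variant) dosage combinations unachievable from parents.

    Only trios fully present in the matrix with non-missing calls are
    audited. A child dosage is achievable when some pair of transmittable
    alleles from the two parental dosages sums to it.
    """
    transmittable = {0: {0}, 1: {0, 1}, 2: {1}}
    achievable = np.zeros((3, 3, 3), dtype=bool)
    for df in range(3):
        for dm in range(3):
            for af in transmittable[df]:
                for am in transmittable[dm]:
                    achievable[df, dm, af + am] = True
    violations = 0
    for m in pedigrees.all_samples():
        if m.father_id is None or m.mother_id is None:
            continue
        if not all(s in matrix.samples for s in (m.sample_id, m.father_id, m.mother_id)):
            continue
        child = matrix.sample_columns([m.sample_id])[:, 0]
        fat = matrix.sample_columns([m.father_id])[:, 0]
        mot = matrix.sample_columns([m.mother_id])[:, 0]
        ok = (child != MISSING) & (fat != MISSING) & (mot != MISSING)
        violations += int(
            (~achievable[fat[ok], mot[ok], child[ok]]).sum()
        )
    return violations


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Emit cohort.vcf, cohort.ped, annotations.tsv, gene sets and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.json",
        "inner_ear": out / "inner_ear.txt",
        "balance": out / "balance.txt",
    }
    write_vcf(cohort.matrix, paths["vcf"], cohort.annotations)
    write_ped(cohort.pedigrees, paths["ped"])
    write_candidates(cohort.annotations, paths["annotations"])
    paths["inner_ear"].write_text(
        "\n".join(sorted(cohort.inner_ear.genes)) + "\n"
    )
    paths["balance"].write_text("\n".join(sorted(cohort.balance.genes)) + "\n")
    truth = {
        "causal_key": str(cohort.truth.causal_key),
        "carrier_samples": sorted(cohort.truth.carrier_samples),
        "carrier_families": sorted(cohort.truth.carrier_families),
        "provenance": dict(sorted(cohort.truth.provenance.items())),
        "seed": cohort.config.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
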