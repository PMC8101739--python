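"""Pairwise relatedness from exome genotypes (KING-robust estimator).

The between-family robust kinship estimate for samples i and j is a
moment estimator built from four genotype-count summaries over markers
genotyped in both samples:

    phi_hat = (N_hethet - 2*N_opp) / (2 * min(N_het_i, N_het_j))
              + 1/2 - (N_het_i + N_het_j) / (4 * min(N_het_i, N_het_j))

where N_hethet counts markers at which both samples are heterozygous,
N_opp counts opposite homozygotes, and N_het_i / N_het_j are per-sample
heterozygote counts. Duplicate genotypes give exactly 0.5; expected
values are 0.25 for parent-offspring, 0.125 for 2nd degree and 0 for
unrelated pairs. The estimator does not require allele frequencies, which
is what makes it robust to population structure.

The screen mirrors a study design in which no two families should share
ancestry closer than 3rd degree: all cross-family pairs are evaluated and
any pair with phi_hat above the threshold (default 0.125) is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, PedigreeSet

#: Kinship boundaries separating duplicate/1st/2nd/3rd degree/unrelated,
#: the conventional inference cutpoints (2^-3/2, 2^-5/2, 2^-7/2, 2^-9/2).
DEGREE_BOUNDARIES = (0.354, 0.177, 0.0884, 0.0442)

DEFAULT_THRESHOLD = 0.125
DEFAULT_MIN_MARKERS = 100
DEFAULT_MIN_MAF = 0.01


@dataclass
class KinshipResult:
    """Pairwise estimate with its genotype-count summaries."""

    sample_i: str
    sample_j: str
    phi: Optional[float]
    n_snps: int
    n_het_i: int
    n_het_j: int
    n_hethet: int
    n_opp: int
    reason: Optional[str] = None  # set when phi is undefined

    def __post_init__(self) -> None:
        if self.n_hethet > min(self.n_het_i, self.n_het_j):
            raise ValueError("N_hethet exceeds a per-sample het count")


def _marker_mask(
    matrix: GenotypeMatrix,
    gi: np.ndarray,
    gj: np.ndarray,
    min_maf: float,
    maf: Optional[np.ndarray],
) -> np.ndarray:
    """Markers non-missing in both samples with MAF >= min_maf.

    When no external MAF vector is supplied, allele frequencies are
    estimated from the full cohort's non-missing calls.
    """
    mask = (gi != MISSING) & (gj != MISSING)
    if maf is None:
        valid = matrix.dosages != MISSING
        with np.errstate(invalid="ignore"):
            af = np.where(
                valid.sum(axis=1) > 0,
                np.where(matrix.dosages == MISSING, 0, matrix.dosages).sum(axis=1)
                / (2.0 * np.maximum(valid.sum(axis=1), 1)),
                0.0,
            )
        maf = np.minimum(af, 1.0 - af)
    return mask & (np.asarray(maf) >= min_maf)


def king_robust_pair(
    matrix: GenotypeMatrix,
    sample_i: str,
    sample_j: str,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_maf: float = DEFAULT_MIN_MAF,
    maf: Optional[np.ndarray] = None,
) -> KinshipResult:
    """KING-robust kinship estimate for one sample pair.

    Markers missing in either sample or with MAF below ``min_maf`` are
    excluded. Fewer than ``min_markers`` usable markers, or a zero
    heterozygote count in either sample, leaves phi undefined (reported
    with a reason rather than raising).
    """
    gi = matrix.dosages[:, matrix.sample_index(sample_i)].astype(np.int16)
    gj = matrix.dosages[:, matrix.sample_index(sample_j)].astype(np.int16)
    mask = _marker_mask(matrix, gi, gj, min_maf, maf)
    gi, gj = gi[mask], gj[mask]
    n_snps = int(mask.sum())
    het_i = int((gi == 1).sum())
    het_j = int((gj == 1).sum())
    n_hethet = int(((gi == 1) & (gj == 1)).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    result = KinshipResult(
        sample_i=sample_i,
        sample_j=sample_j,
        phi=None,
        n_snps=n_snps,
        n_het_i=het_i,
        n_het_j=het_j,
        n_hethet=n_hethet,
        n_opp=n_opp,
    )
    if n_snps < min_markers:
        result.reason = f"only {n_snps} usable markers (< {min_markers})"
        return result
    min_het = min(het_i, het_j)
    if min_het == 0:
        result.reason = "zero heterozygote count in a sample"
        return result
    result.phi = (
        (n_hethet - 2.0 * n_opp) / (2.0 * min_het)
        + 0.5
        - (het_i + het_j) / (4.0 * min_het)
    )
    return result


@dataclass
class KinshipScreen:
    """Cross-family relatedness screen output."""

    flagged: list[KinshipResult]
    max_between_phi: Optional[float]
    between: list[KinshipResult]
    within: list[KinshipResult]
    threshold: float


def kinship_screen(
    matrix: GenotypeMatrix,
    pedigrees: PedigreeSet,
    threshold: float = DEFAULT_THRESHOLD,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_maf: float = DEFAULT_MIN_MAF,
) -> KinshipScreen:
    """Evaluate all cross-family pairs; flag phi above the threshold.

    Within-family pairs are evaluated too and reported separately as a
    positive control (they should show elevated kinship). A threshold of
    0.125 flags anything closer than 3rd degree.
    """
    sample_family = {m.sample_id: m.family_id for m in pedigrees.all_samples()}
    ids = [s for s in matrix.samples if s in sample_family]
    between: list[KinshipResult] = []
    within: list[KinshipResult] = []
    # Cohort allele frequencies computed once for all pairs.
    valid = matrix.dosages != MISSING
    counts = np.maximum(valid.sum(axis=1), 1)
    af = np.where(matrix.dosages == MISSING, 0, matrix.dosages).sum(axis=1) / (2.0 * counts)
    maf = np.minimum(af, 1.0 - af)
    for i_idx in range(len(ids)):
        for j_idx in range(i_idx + 1, len(ids)):
            si, sj = ids[i_idx], ids[j_idx]
            result = king_robust_pair(
                matrix, si, sj, min_markers=min_markers, min_maf=min_maf, maf=maf
            )
            if sample_family[si] == sample_family[sj]:
                within.append(result)
            else:
                between.append(result)
    defined = [r.phi for r in between if r.phi is not None]
    flagged = [r for r in between if r.phi is not None and r.phi > threshold]
    return KinshipScreen(
        flagged=flagged,
        max_between_phi=max(defined) if defined else None,
        between=between,
        within=within,
        threshold=threshold,
    )


def write_kinship_tsv(screen: KinshipScreen, pedigrees: PedigreeSet, path) -> None:
    sample_family = {m.sample_id: m.family_id for m in pedigrees.all_samples()}
    with open(path, "w") as fh:
        fh.write("ID1\tID2\tFID1\tFID2\tNSNP\tPHI\tFLAG\n")
        for r in screen.between + screen.within:
            phi = f"{r.phi:.6g}" if r.phi is not None else "NA"
            flag = (
                "1"
                if r.phi is not None
                and r.phi > screen.threshold
                and sample_family[r.sample_i] != sample_family[r.sample_j]
                else "0"
            )
            fh.write(
                f"{r.sample_i}\t{r.sample_j}\t{sample_family[r.sample_i]}\t"
                f"{sample_family[r.sample_j]}\t{r.n_snps}\t{phi}\t{flag}\n"
            )
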