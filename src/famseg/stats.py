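"""Association and descriptive statistics for proband carrier counts.

The central statistic is the exact two-tailed Fisher test on a 2x2 table
of carrier-positive/negative probands (cases vs one control source),
computed by hypergeometric enumeration with the minimum-likelihood
two-sided rule: the p-value sums the point probabilities of every table
with the same margins whose probability does not exceed the observed
table's (within relative tolerance 1e-7). Probabilities are evaluated in
log-space so large public-database margins stay stable.

Also here: carrier fraction and penetrance summaries, a two-sample t-test
that accepts either raw values or (mean, sd, n) summaries, and one-way
ANOVA with Bonferroni-adjusted pairwise comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .datamodel import (
    ContingencyTable2x2,
    GenotypeMatrix,
    PedigreeSet,
    VariantKey,
)

logger = logging.getLogger(__name__)

_REL_TOL = 1e-7


@dataclass
class AssociationResult:
    """One case/control comparison for a candidate variant."""

    table: ContingencyTable2x2
    p_two_tailed: float
    odds_ratio: float
    source: str
    or_corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError(f"p out of [0,1]: {self.p_two_tailed}")


@dataclass
class GroupSummary:
    """Summary triple (mean, sd, n) for one group of onset ages."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"negative sd: {self.sd}")


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Exact two-tailed Fisher p for a 2x2 table.

    Enumerates the hypergeometric distribution over the table's support
    and sums every point probability <= the observed one (relative
    tolerance 1e-7), the minimum-likelihood convention of mainstream
    statistical software.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n == 0:
        raise ValueError("zero grand total")
    row1 = a + b
    col1 = a + c
    # support of the (0,0) cell given fixed margins
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    logpmf = sps.hypergeom.logpmf(support, n, col1, row1)
    log_obs = sps.hypergeom.logpmf(a, n, col1, row1)
    include = logpmf <= log_obs + math.log1p(_REL_TOL)
    if include.all():  # whole support counted: exactly 1 by construction
        return 1.0
    logp = np.logaddexp.reduce(logpmf[include])
    return float(min(1.0, math.exp(logp)))


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Sample odds ratio; Haldane-Anscombe 0.5 added only when a cell is 0."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def _proband_dosages(
    pedigrees: PedigreeSet,
    matrix: GenotypeMatrix,
    key: VariantKey,
    family_ids: Sequence[str],
) -> tuple[int, int, list[str]]:
    """(carrier, non-carrier, dropped-family) counts over designated probands."""
    pos = neg = 0
    dropped: list[str] = []
    for fid in family_ids:
        proband = pedigrees.proband(fid)
        if proband is None or proband.sample_id not in matrix.samples:
            dropped.append(fid)
            continue
        dose = matrix.dosage(key, proband.sample_id)
        if dose < 0:
            logger.warning(
                "family %s dropped: proband %s genotype missing at %s",
                fid, proband.sample_id, key,
            )
            dropped.append(fid)
            continue
        if dose >= 1:
            pos += 1
        else:
            neg += 1
    return pos, neg, dropped


def sample_control_counts(
    pedigrees: PedigreeSet, matrix: GenotypeMatrix, key: VariantKey
) -> tuple[int, int]:
    """Carrier/non-carrier counts over non-BPPV-family probands."""
    pos, neg, _ = _proband_dosages(
        pedigrees, matrix, key, pedigrees.control_family_ids()
    )
    return pos, neg


def build_family_table(
    pedigrees: PedigreeSet,
    matrix: GenotypeMatrix,
    key: VariantKey,
    control: tuple[int, int],
) -> ContingencyTable2x2:
    """One proband per case family vs a control source.

    ``a`` counts case-family probands with dosage >= 1, ``b`` those with
    dosage 0; ``(c, d)`` are the control source's positive/negative counts
    as given (sample non-BPPV probands or public-database counts).
    Families whose proband genotype is missing are dropped from both
    margins with a logged warning.
    """
    pos, neg, _ = _proband_dosages(pedigrees, matrix, key, pedigrees.case_family_ids())
    return ContingencyTable2x2(a=pos, b=neg, c=int(control[0]), d=int(control[1]))


def associate(
    pedigrees: PedigreeSet,
    matrix: GenotypeMatrix,
    key: VariantKey,
    control_sources: Iterable[tuple[str, int, int]],
) -> list[AssociationResult]:
    """Fisher association of a candidate against each control source."""
    out = []
    for source, pos, neg in control_sources:
        table = build_family_table(pedigrees, matrix, key, (pos, neg))
        p = fisher_exact_two_tailed(table)
        ratio, corrected = odds_ratio(table)
        out.append(
            AssociationResult(
                table=table,
                p_two_tailed=p,
                odds_ratio=ratio,
                source=source,
                or_corrected=corrected,
            )
        )
    return out


def carrier_fraction(
    pedigrees: PedigreeSet, matrix: GenotypeMatrix, key: VariantKey
) -> tuple[int, int, int]:
    """(carrier families, total case families, percent to nearest integer)."""
    fids = pedigrees.case_family_ids()
    if not fids:
        raise ValueError("no case families")
    pos, neg, dropped = _proband_dosages(pedigrees, matrix, key, fids)
    total = pos + neg
    if total == 0:
        raise ValueError("all case-family probands missing at this variant")
    return pos, total, carrier_percent(pos, total)


def carrier_percent(carriers: int, total: int) -> int:
    """Percent of carrier families, rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("zero families")
    return int(round(100.0 * carriers / total))


def penetrance_estimate(
    pedigrees: PedigreeSet, matrix: GenotypeMatrix, key: VariantKey
) -> float:
    """Affected carriers / all genotyped carriers of known phenotype.

    Carriers of unknown affection are excluded from both numerator and
    denominator. Raises if no informative carrier exists.
    """
    affected = carriers = 0
    for m in pedigrees.all_samples():
        if m.sample_id not in matrix.samples:
            continue
        dose = matrix.dosage(key, m.sample_id)
        if dose < 1 or m.affection == "unknown":
            continue
        carriers += 1
        if m.affection == "affected":
            affected += 1
    if carriers == 0:
        raise ValueError(f"no genotyped carriers of known phenotype at {key}")
    return affected / carriers


GroupLike = Union[GroupSummary, Sequence[float], np.ndarray]


def _summarize(group: GroupLike) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    arr = np.asarray(group, dtype=float)
    if arr.size < 2:
        raise ValueError("group needs n >= 2")
    return GroupSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


def t_test_two_sample(
    g1: GroupLike, g2: GroupLike, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t-test from raw values or (mean, sd, n) summaries.

    ``variant="pooled"`` is the classical Student test (equal variances);
    ``"welch"`` uses the Welch-Satterthwaite degrees of freedom. Returns
    (t, df, two-tailed p). Two zero-variance groups with equal means give
    p = 1 by convention; zero variance with unequal means is an error.
    """
    s1, s2 = _summarize(g1), _summarize(g2)
    if s1.sd == 0.0 and s2.sd == 0.0:
        if s1.mean == s2.mean:
            return 0.0, float(s1.n + s2.n - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "pooled":
        df = s1.n + s2.n - 2
        sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / df
        se = math.sqrt(sp2 * (1.0 / s1.n + 1.0 / s2.n))
    elif variant == "welch":
        v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = (s1.mean - s2.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(1.0, p))


def anova_one_way_bonferroni(
    groups: Sequence[Sequence[float]],
) -> tuple[float, int, int, float, dict[tuple[int, int], float]]:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons.

    Returns (F, df_between, df_within, p, pairwise) where ``pairwise``
    maps group-index pairs to adjusted p-values. Pairwise tests use the
    pooled within-group mean square from the full ANOVA as the error term
    (the classical Bonferroni post hoc); raw p-values are multiplied by
    the number of pairs and capped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise ValueError(f"group {i} has n < 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df1, df2 = k - 1, n_total - k
    f_stat, p = sps.f_oneway(*arrays)
    if math.isnan(f_stat):  # all observations identical
        f_stat, p = 0.0, 1.0
    mse = sum((a.size - 1) * a.var(ddof=1) for a in arrays) / df2
    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0.0:
                raw = 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0
            else:
                se = math.sqrt(mse * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
                t = (arrays[i].mean() - arrays[j].mean()) / se
                raw = 2.0 * sps.t.sf(abs(t), df2)
            pairwise[(i, j)] = min(1.0, raw * n_pairs)
    return float(f_stat), df1, df2, float(p), pairwise
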