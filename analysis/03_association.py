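"""Association statistics: published counts and the simulated cohort.

Part 1 reproduces the published 2x2 Fisher comparisons from
data/table1_counts.tsv — 13/29 carrier-positive/negative case-family
probands against three control sources (1/49 sample controls, 11/2739
ExAC, 476/3054 NHLBI European Americans) — plus the carrier fraction
among case families.

Part 2 computes the same statistics on the simulated cohort: the proband
contingency table against the simulated non-BPPV families, the carrier
fraction, the penetrance estimate among genotyped carriers, and the
onset-age comparison of affected carriers versus affected non-carriers.

Writes results/table1_association.tsv and results/cohort_association.tsv.
"""

import json
from pathlib import Path

from famseg.datamodel import VariantKey
from famseg.io import read_count_table, read_ped, read_vcf
from famseg.pipeline import reproduce_table1, write_association_tsv
from famseg.stats import (
    associate,
    carrier_fraction,
    carrier_percent,
    penetrance_estimate,
    sample_control_counts,
    t_test_two_sample,
)

ROOT = Path(__file__).resolve().parents[1]
BASE = ROOT / "results"


def main() -> None:
    counts_file = ROOT / "data" / "table1_counts.tsv"
    print("published proband counts, two-tailed Fisher per control source:")
    results = reproduce_table1(counts_file, BASE / "table1_association.tsv")
    for r in results:
        t = r.table
        print(f"  vs {r.source}: {t.a}/{t.b} | {t.c}/{t.d} "
              f"OR={r.odds_ratio:.3g} p={r.p_two_tailed:.3g}")
    case = [r for r in read_count_table(counts_file) if r[0] == "BPPV"][0]
    pct = carrier_percent(case[1], case[1] + case[2])
    print(f"  carrier fraction: {case[1]} of {case[1] + case[2]} case families = {pct}%")

    cohort_dir = BASE / "cohort"
    matrix, _ = read_vcf(cohort_dir / "cohort.vcf")
    pedigrees = read_ped(cohort_dir / "cohort.ped")
    causal = VariantKey.parse(
        json.loads((cohort_dir / "truth.json").read_text())["causal_key"]
    )
    pos, neg = sample_control_counts(pedigrees, matrix, causal)
    results = associate(pedigrees, matrix, causal, [("simulated_controls", pos, neg)])
    write_association_tsv(results, BASE / "cohort_association.tsv")
    r = results[0]
    t = r.table
    print(f"simulated cohort, candidate {causal}:")
    print(f"  probands {t.a}/{t.b} vs control families {t.c}/{t.d}: "
          f"OR={r.odds_ratio:.3g} p={r.p_two_tailed:.3g}")
    carriers, total, pct = carrier_fraction(pedigrees, matrix, causal)
    print(f"  carrier fraction: {carriers}/{total} families = {pct}%")
    pen = penetrance_estimate(pedigrees, matrix, causal)
    print(f"  penetrance among genotyped carriers: {pen:.3f}")

    carrier_ids = {s for s in matrix.samples if matrix.dosage(causal, s) >= 1}
    onset_carrier = [s.onset_age for s in pedigrees.all_samples()
                     if s.onset_age is not None and s.sample_id in carrier_ids]
    onset_noncarrier = [s.onset_age for s in pedigrees.all_samples()
                        if s.onset_age is not None and s.sample_id not in carrier_ids]
    if len(onset_carrier) >= 2 and len(onset_noncarrier) >= 2:
        tstat, df, p = t_test_two_sample(onset_carrier, onset_noncarrier)
        print(f"  onset ages: carriers n={len(onset_carrier)} vs "
              f"non-carriers n={len(onset_noncarrier)}, "
              f"t={tstat:.2f} df={df:.0f} p={p:.3g}")


if __name__ == "__main__":
    main()
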