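# Methods

## Problem setting

`famseg` implements a family-based strategy for finding rare variants
that heighten susceptibility to a common, late-onset, autosomal-dominant
phenotype with reduced penetrance — the motivating application is
familial benign paroxysmal positional vertigo (BPPV), where multiplex
families are ascertained for two or more affected relatives and exome
sequencing is performed on a subset of affected members, unaffected
relatives, and independent elderly controls. Because such a phenotype is
genetically heterogeneous (different families may segregate different
risk alleles), each family is analysed on its own before any
cross-family comparison.

## The tiered filter

Candidate selection runs in four tiers over a dosage matrix (alternate
allele count 0/1/2 per sample per variant, -1 for a missing call):

1. **Impact prefilter.** Variants whose annotated impact class is LOW or
   MODIFIER are dropped; variants with no impact annotation are kept.
   Impact classes are inputs (SnpEff-style), never computed here.
2. **Per-family segregation.** Within each case family, keep a variant
   when every affected member carries it *in the same zygosity state*
   (all heterozygous, or all homozygous) and every unaffected member has
   dosage 0. The zygosity-state condition (`zygosity_strict`, default
   on) encodes the idea that a dominant allele shared by descent appears
   in one state; a relaxed carrier-based mode is available for
   sensitivity analyses. Families with no unaffected member of their own
   borrow the cohort's designated independent controls as unaffecteds —
   the assignment is explicit (PED `CONTROL` column), never implicit. A
   missing call in any family member removes the variant for that family
   under the default `exclude_variant` policy (conservative);
   `treat_as_noncarrier` is available.
3. **Rarity / deleteriousness.** Keep candidates with MAF < 0.05 **or**
   CADD > 9. Both thresholds are deliberately lenient: under genetic
   heterogeneity and a lifetime prevalence of ~10%, a stringent
   frequency cut would discard true risk alleles. A variant with no
   recorded MAF is treated as rare (novel allele, standard convention);
   a variant with no CADD score cannot pass the CADD clause.
4. **Cross-family exclusion and prioritization.** A candidate carried by
   *any* unaffected individual or independent control anywhere in the
   cohort is removed: under a dominant model, an unaffected carrier is
   the only observation that directly contradicts the candidate. A
   stricter reading — also removing candidates absent from affected
   members of other candidate families — is available behind
   `exclude_on_affected_noncarrier` but off by default, since affected
   non-carriers are expected under heterogeneity. Survivors receive
   three flags: shared by ≥ 2 families, gene in the inner-ear
   expression set, gene in the balance/hearing set; any flag
   prioritizes. The output order is a deterministic total order (flag
   count desc, sharing families desc, CADD desc, coordinate asc) so runs
   are reproducible under input shuffling.

## Association statistics

Carrier counts use **one proband per family** so that related
individuals never inflate the allele-frequency comparison. The proband
is the flagged member; without a flag the earliest-onset affected
member, then the lexicographically first affected member (the fallback
order is fixed and logged). The 2×2 table (case probands carrier/non-
carrier vs a control source) is tested with a two-tailed Fisher exact
test implemented by hypergeometric enumeration with the minimum-
likelihood rule: all tables with the observed margins whose point
probability is ≤ the observed table's (relative tolerance 1e-7)
contribute to p. Probabilities are evaluated in log-space so that
public-database margins in the thousands remain stable; when the whole
support qualifies the p-value is exactly 1. This is the convention of
mainstream statistical software (R's `fisher.test`, scipy), and the
implementation is verified in the tests against full enumeration on
every table with grand total ≤ 40 and against scipy on random tables.
The odds ratio applies the Haldane–Anscombe 0.5 correction only when a
cell is zero, and says so.

Control sources are of two kinds and are treated identically as
positive/negative unit counts: probands of phenotype-free control
families, and public-database counts passed through verbatim as printed
(the units of database entries are not reinterpreted).

Descriptive summaries: the **carrier fraction** is carrier probands over
case families, reported as an integer percent; the **penetrance
estimate** is affected carriers over all genotyped carriers of known
phenotype, cohort-wide (unknown-phenotype carriers are excluded from
numerator and denominator — one of several possible tallies, chosen for
being definitional). Onset-age comparisons use a two-sample t-test
(classical pooled by default, Welch optional) accepting either raw ages
or (mean, sd, n) summaries; expression-level group comparisons use
one-way ANOVA with Bonferroni-adjusted pairwise contrasts computed from
the pooled within-group mean square.

## Kinship screening

Cross-family relatedness is screened with the KING-robust between-family
estimator computed from four genotype-count summaries over markers
non-missing in both samples (markers with MAF < 0.01 are excluded; the
floor is 100 usable markers):

    phi = (N_hethet − 2·N_opp) / (2·min(N_het_i, N_het_j))
          + 1/2 − (N_het_i + N_het_j) / (4·min(N_het_i, N_het_j))

Duplicate genotypes give exactly 0.5 by algebra; parent-offspring,
second-degree and unrelated pairs have expectations 0.25, 0.125 and 0.
Any cross-family pair with phi > 0.125 (closer than 3rd degree) is
flagged; within-family pairs are reported separately as positive
controls. Numerical property worth knowing: because the denominator uses
min(N_het_i, N_het_j) and min ≤ mean, the estimator carries a small
negative bias of order E|N_het_i − N_het_j| / (4·N_het) — about −0.004
at 10,000 markers for samples with equal expected heterozygosity. The
calibration tests therefore compare the replicate mean against the
expectation at the scale of the replicate standard deviation (±0.02–0.03
for single pairs), not at the scale of the standard error of the mean,
which the intrinsic bias would always exceed.

## The cohort simulator

The generator produces cohorts with the statistical structure the
analysis assumes, not sequence-level realism. Defaults encode the
emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_case_families` | 12 | multiplex case families |
| `family_templates` | 12 pairs | (affected, unaffected) sequenced per family; defaults sum to 28 + 7 |
| `n_control_families` | 50 | phenotype-free 2-member families |
| `n_independent_controls` | 7 | family-less elderly controls |
| `n_background_variants` | 5000 | unlinked exonic background |
| background MAF | 0.7·Beta(0.2, 8) + 0.3·U(0.05, 0.5) | rare-skewed site-frequency mixture |
| `causal_maf` | 0.005 | population frequency of the risk allele |
| `penetrance` | 0.95 | P(affected \| carrier) |
| `phenocopy_rate` | 0.02 | P(affected \| non-carrier) |
| onset ages | N(44.0, 14.0²) / N(54.4, 16.1²) | carriers / non-carrier affecteds, years |
| `female_fraction` | 0.68 | ≈ 2.1 : 1 female/male |
| impact classes | HIGH .03 / MODERATE .25 / LOW .30 / MODIFIER .42 | annotation mixture |
| CADD | U(0, 40) | annotation score |

Founders draw background genotypes in Hardy–Weinberg proportions;
children receive one allele per parent with probability dosage/2 per
unlinked site (gene drop). The causal variant is planted heterozygous in
one founder of every case family — mirroring ascertainment of multiplex
families — while control families and independent controls draw it at
`causal_maf`. Affection is penetrant carriage or phenocopy.

Ascertainment is modelled by rejection sampling, as in the emulated
study design: case families are redrawn until ≥ 2 members are affected
(`ascertain_min_affected`), control families and independent controls
until no member is affected. Two consequences matter for interpretation.
First, at penetrance 1.0 a control-family carrier would necessarily be
affected, so ascertained control families never carry the causal allele
— which is why the noise-free recovery experiments are deterministic.
Second, conditioning case families on ≥ 2 affected members biases the
*within-cohort* carrier affection rate above the generative penetrance
(classical ascertainment bias), so the simulator-fidelity checks of the
penetrance mechanism run with ascertainment disabled.

What the generator does **not** emulate: linkage disequilibrium and
recombination (no analysis step uses LD), sequencing error profiles,
population stratification, age-dependent penetrance, X-linked or
recessive inheritance. Passing recovery tests therefore show that the
funnel's logic is correct under its own model assumptions — they do not
show robustness to LD-induced shadow candidates or to structured
control cohorts, which real data would add.

## Numerical and design choices

* Genotypes are unphased dosages in an int8 matrix (missing = −1); no
  pipeline step uses phase. Multi-allelic VCF records are split into
  biallelic keys before any filtering, conserving per-sample alternate
  dosage at the site.
* Annotations may come from VCF INFO or a side TSV; on conflict the side
  TSV wins per field (decouples the pipeline from annotator INFO
  dialects).
* VCF parse errors name the record coordinate and record index (the
  reader is built on cyvcf2, which does not expose raw line numbers).
* All tie-breaks in prioritization are explicit; every run with the same
  inputs and seed produces byte-identical numeric outputs, and `run_all`
  writes a manifest (config, input digests, seed, stage counts) with
  every report.
* Simulated problem sizes in the test suite and the acceptance script
  (e.g. 150 background variants in the 100-run recovery loops, 400
  variants in Mendelian audits) are chosen as the smallest cohorts that
  exercise the logic; condition parameters (penetrance, causal MAF,
  family counts, templates) always stay at the study-condition defaults.

## Known limitations

* The penetrance estimator counts each genotyped carrier once,
  cohort-wide; other tallies (per-family, obligate-carrier imputation)
  would give different values on pedigrees with ungenotyped members.
* Recomputing a pooled t-test from rounded summary statistics need not
  reproduce a p-value computed from full-precision raw values; the
  onset-age comparison is therefore validated against closed-form
  oracles, not against any particular published raw-data value.
* The cross-family "contradiction" rule has two defensible readings (see
  tier 4); both are implemented, and the default is the weaker one.
* With reduced penetrance the strict filter can eliminate a true risk
  variant when a non-penetrant carrier happens to be among the sequenced
  unaffected relatives — the showcase run in `analysis/` demonstrates
  exactly this failure mode. That is a property of the method being
  implemented, not a defect of the implementation.
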