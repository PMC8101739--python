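"""Tiered filter behaviour, brute-force oracle equivalence, invariances."""

import numpy as np
import pytest

from famseg.datamodel import (
    GeneSet,
    GenotypeMatrix,
    PedigreeSet,
    Sample,
    VariantAnnotation,
    VariantKey,
)
from famseg.filtering import (
    FilterConfig,
    SharedState,
    cross_family_exclusion,
    family_segregation,
    freq_impact_filter,
    impact_prefilter,
    prioritize,
    run_tiered_pipeline,
)
from famseg.simulate import SimulationConfig, simulate_cohort

from ._oracles import brute_force_tiers


def make_key(pos):
    return VariantKey("chr5", pos, "A", "G")


class TestImpactPrefilter:
    @pytest.mark.parametrize(
        "impact,kept",
        [("HIGH", True), ("MODERATE", True), ("LOW", False),
         ("MODIFIER", False), (None, True)],
    )
    def test_default_impact_policy(self, impact, kept):
        ann = [VariantAnnotation(key=make_key(1), impact=impact)]
        result = impact_prefilter(ann, FilterConfig())
        assert (make_key(1) in result) is kept


class TestFamilySegregation:
    def test_shared_het_with_clear_unaffected(self, toy_family):
        members, matrix, _ = toy_family
        states = family_segregation(members, matrix, FilterConfig())
        assert SharedState(make_key(100), "het") in states

    def test_zygosity_conflict_excluded_when_strict(self, toy_family):
        members, matrix, _ = toy_family
        states = family_segregation(members, matrix, FilterConfig())
        assert all(s.key != make_key(200) for s in states)

    def test_zygosity_conflict_kept_when_relaxed(self, toy_family):
        members, matrix, _ = toy_family
        states = family_segregation(
            members, matrix, FilterConfig(zygosity_strict=False)
        )
        assert SharedState(make_key(200), "het") in states

    def test_shared_hom_state_recorded(self, toy_family):
        members, matrix, _ = toy_family
        states = family_segregation(members, matrix, FilterConfig())
        assert SharedState(make_key(300), "hom") in states

    def test_unaffected_carrier_excluded(self, toy_family):
        members, matrix, _ = toy_family
        states = family_segregation(members, matrix, FilterConfig())
        assert all(s.key != make_key(400) for s in states)

    def test_missing_policy(self, toy_family):
        members, matrix, _ = toy_family
        strict = family_segregation(members, matrix, FilterConfig())
        assert all(s.key != make_key(500) for s in strict)
        lenient = family_segregation(
            members, matrix, FilterConfig(missing_policy="treat_as_noncarrier")
        )
        # A2's missing call becomes dosage 0, breaking the shared-het rule
        assert all(s.key != make_key(500) for s in lenient)

    def test_borrowed_controls_act_as_unaffecteds(self, toy_family):
        members, matrix, _ = toy_family
        family = [m for m in members if m.affection == "affected"]
        control = Sample(
            sample_id="U1", family_id="CTRL", affection="unaffected",
            is_independent_control=True,
        )
        states = family_segregation(
            family, matrix, FilterConfig(), extra_unaffected=[control]
        )
        assert all(s.key != make_key(400) for s in states)

    def test_no_affected_members_is_error(self, toy_family):
        members, matrix, _ = toy_family
        unaffected_only = [m for m in members if m.affection == "unaffected"]
        with pytest.raises(ValueError, match="no affected"):
            family_segregation(unaffected_only, matrix, FilterConfig())


class TestFreqImpactFilter:
    @pytest.mark.parametrize(
        "maf,cadd,kept",
        [
            (0.001, 2.0, True),   # rare, benign -> MAF clause
            (0.2, 15.0, True),    # common, deleterious -> CADD clause
            (0.2, 5.0, False),    # common, benign -> dropped
            (None, 5.0, True),    # novel allele counts as rare
            (0.2, None, False),   # absent CADD fails the CADD clause
        ],
    )
    def test_rarity_or_deleteriousness(self, maf, cadd, kept):
        key = make_key(1)
        cand = {SharedState(key, "het")}
        ann = [VariantAnnotation(key=key, maf=maf, cadd=cadd)]
        result = freq_impact_filter(cand, ann, FilterConfig())
        assert (SharedState(key, "het") in result) is kept


class TestCrossFamilyExclusion:
    def _two_family_setup(self, unaffected_dosage):
        key = make_key(100)
        fam_a = [
            Sample(sample_id="A1", family_id="FA", affection="affected"),
            Sample(sample_id="A2", family_id="FA", affection="affected"),
        ]
        fam_b = [
            Sample(sample_id="B1", family_id="FB", affection="affected"),
            Sample(sample_id="B2", family_id="FB", affection="unaffected"),
        ]
        matrix = GenotypeMatrix(
            variants=[key],
            samples=["A1", "A2", "B1", "B2"],
            dosages=np.array([[1, 1, 0, unaffected_dosage]], dtype=np.int8),
        )
        ped = PedigreeSet(families={"FA": fam_a, "FB": fam_b})
        per_family = {"FA": {SharedState(key, "het")}}
        return key, per_family, ped, matrix

    def test_unaffected_carrier_elsewhere_excludes(self):
        key, per_family, ped, matrix = self._two_family_setup(unaffected_dosage=1)
        assert cross_family_exclusion(per_family, ped, matrix) == set()

    def test_clean_candidate_retained(self):
        key, per_family, ped, matrix = self._two_family_setup(unaffected_dosage=0)
        assert cross_family_exclusion(per_family, ped, matrix) == {key}

    def test_empty_input_gives_empty_set(self):
        _, _, ped, matrix = self._two_family_setup(0)
        assert cross_family_exclusion({}, ped, matrix) == set()

    def test_affected_noncarrier_interpretation_flag(self):
        # B1 (affected, other family) lacks the variant: only the stricter
        # interpretation removes the candidate.
        key, per_family, ped, matrix = self._two_family_setup(unaffected_dosage=0)
        strict = cross_family_exclusion(
            per_family, ped, matrix,
            FilterConfig(exclude_on_affected_noncarrier=True),
        )
        assert strict == set()


class TestPrioritize:
    def _setup(self):
        k1, k2, k3 = make_key(1), make_key(2), make_key(3)
        ann = [
            VariantAnnotation(key=k1, gene="AAA", cadd=30.0),
            VariantAnnotation(key=k2, gene="BBB", cadd=10.0),
            VariantAnnotation(key=k3, gene="CCC", cadd=20.0),
        ]
        per_family = {
            "F1": {SharedState(k1, "het"), SharedState(k2, "het"), SharedState(k3, "het")},
            "F2": {SharedState(k1, "het"), SharedState(k2, "het")},
            "F3": {SharedState(k1, "het")},
        }
        inner = GeneSet(name="i", genes=frozenset({"AAA"}))
        balance = GeneSet(name="b", genes=frozenset({"AAA"}))
        return (k1, k2, k3), per_family, inner, balance, ann

    def test_flags_and_rank(self):
        keys, per_family, inner, balance, ann = self._setup()
        k1, k2, k3 = keys
        out = prioritize(set(keys), per_family, inner, balance, ann, FilterConfig())
        assert out[0].key == k1 and out[0].rank == 1
        assert out[0].flags == {"multi_family": True, "inner_ear": True, "balance": True}
        assert [p.key for p in out] == [k1, k2]  # k3: one family, no set hit

    def test_unflagged_not_prioritized(self):
        keys, per_family, inner, balance, ann = self._setup()
        out = prioritize(set(keys), per_family, inner, balance, ann, FilterConfig())
        assert all(p.key != keys[2] for p in out)

    def test_cadd_tiebreak_deterministic(self):
        k1, k2 = make_key(10), make_key(20)
        ann = [
            VariantAnnotation(key=k1, gene="X1", cadd=5.0),
            VariantAnnotation(key=k2, gene="X2", cadd=15.0),
        ]
        per_family = {
            "F1": {SharedState(k1, "het"), SharedState(k2, "het")},
            "F2": {SharedState(k1, "het"), SharedState(k2, "het")},
        }
        inner = GeneSet(name="i", genes=frozenset({"ZZZ"}))
        out = prioritize({k1, k2}, per_family, inner, inner, ann, FilterConfig())
        assert [p.key for p in out] == [k2, k1]  # higher CADD first


class TestPipeline:
    def test_oracle_equivalence_on_small_cohorts(self):
        """Vectorized funnel equals direct predicate evaluation per variant."""
        for seed in range(5):
            cohort = simulate_cohort(
                SimulationConfig(
                    seed=seed, n_case_families=4, n_control_families=3,
                    n_background_variants=45, n_independent_controls=2,
                )
            )
            config = FilterConfig()
            report = run_tiered_pipeline(
                cohort.matrix, cohort.annotations, cohort.pedigrees,
                cohort.inner_ear, cohort.balance, config,
            )
            per_family, after_freq, survivors, prioritized = brute_force_tiers(
                cohort.matrix, cohort.annotations, cohort.pedigrees,
                cohort.inner_ear, cohort.balance, config,
            )
            assert {f: {(s.key, s.state) for s in v}
                    for f, v in report.per_family_candidates.items()} == per_family
            assert {f: {(s.key, s.state) for s in v}
                    for f, v in report.after_freq_impact.items()} == after_freq
            assert report.after_cross_family == survivors
            assert {p.key for p in report.prioritized} == prioritized

    def test_monotonicity(self, small_cohort):
        report = run_tiered_pipeline(
            small_cohort.matrix, small_cohort.annotations, small_cohort.pedigrees,
            small_cohort.inner_ear, small_cohort.balance, FilterConfig(),
        )
        for fid, after in report.after_freq_impact.items():
            assert after <= report.per_family_candidates[fid]
        freq_keys = {s.key for v in report.after_freq_impact.values() for s in v}
        assert report.after_cross_family <= freq_keys
        assert {p.key for p in report.prioritized} <= report.after_cross_family

    def test_permutation_invariance(self, ideal_cohort):
        """Shuffling samples and variants must not change the report."""
        cohort = ideal_cohort
        rng = np.random.default_rng(0)
        v_perm = rng.permutation(cohort.matrix.n_variants)
        s_perm = rng.permutation(cohort.matrix.n_samples)
        shuffled = GenotypeMatrix(
            variants=[cohort.matrix.variants[i] for i in v_perm],
            samples=[cohort.matrix.samples[j] for j in s_perm],
            dosages=cohort.matrix.dosages[np.ix_(v_perm, s_perm)],
        )
        fids = list(cohort.pedigrees.families)
        shuffled_ped = PedigreeSet(
            families={f: cohort.pedigrees.families[f] for f in reversed(fids)}
        )
        ann_shuffled = [cohort.annotations[i] for i in rng.permutation(len(cohort.annotations))]
        base = run_tiered_pipeline(
            cohort.matrix, cohort.annotations, cohort.pedigrees,
            cohort.inner_ear, cohort.balance, FilterConfig(),
        )
        alt = run_tiered_pipeline(
            shuffled, ann_shuffled, shuffled_ped,
            cohort.inner_ear, cohort.balance, FilterConfig(),
        )
        assert base.per_family_candidates == alt.per_family_candidates
        assert base.after_cross_family == alt.after_cross_family
        assert [(p.key, p.rank) for p in base.prioritized] == [
            (p.key, p.rank) for p in alt.prioritized
        ]

    def test_planted_variant_recovered_in_ideal_cohort(self, ideal_cohort):
        report = run_tiered_pipeline(
            ideal_cohort.matrix, ideal_cohort.annotations, ideal_cohort.pedigrees,
            ideal_cohort.inner_ear, ideal_cohort.balance, FilterConfig(),
        )
        assert any(p.key == ideal_cohort.truth.causal_key for p in report.prioritized)

    def test_missing_sample_in_matrix_is_error(self, ideal_cohort):
        cohort = ideal_cohort
        truncated = GenotypeMatrix(
            variants=cohort.matrix.variants,
            samples=cohort.matrix.samples[:-1],
            dosages=cohort.matrix.dosages[:, :-1],
        )
        missing_id = cohort.matrix.samples[-1]
        with pytest.raises(ValueError, match=missing_id):
            run_tiered_pipeline(
                truncated, cohort.annotations, cohort.pedigrees,
                cohort.inner_ear, cohort.balance, FilterConfig(),
            )

    def test_empty_variant_set_gives_empty_tiers(self, ideal_cohort):
        cohort = ideal_cohort
        empty = GenotypeMatrix(
            variants=[], samples=cohort.matrix.samples,
            dosages=np.empty((0, cohort.matrix.n_samples), dtype=np.int8),
        )
        report = run_tiered_pipeline(
            empty, [], cohort.pedigrees,
            cohort.inner_ear, cohort.balance, FilterConfig(),
        )
        assert report.counts["segregating_union"] == 0
        assert report.counts["prioritized"] == 0
        assert report.after_cross_family == set()
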