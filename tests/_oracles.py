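"""Independent brute-force re-derivations used as test oracles.

Everything here evaluates the filtering predicates directly, per variant
and per sample, with plain Python loops — deliberately sharing no code
with famseg.filtering.
"""

from famseg.datamodel import MISSING


def brute_force_tiers(matrix, annotations, pedigrees, inner_ear, balance, config):
    """Direct per-variant evaluation of the four-tier funnel.

    Returns (per_family, after_freq, survivors, prioritized_keys) where
    per_family maps family -> {(key, state)}.
    """
    ann = {a.key: a for a in annotations}
    controls = [s for s in pedigrees.all_samples() if s.is_independent_control]

    def dosage(key, sid):
        return matrix.dosages[matrix.variant_index(key), matrix.sample_index(sid)]

    impact_pass = set()
    for a in annotations:
        if a.impact is None or a.impact not in config.dropped_impacts:
            impact_pass.add(a.key)

    per_family = {}
    for fid in pedigrees.case_family_ids():
        members = list(pedigrees.families[fid])
        if not any(m.affection == "unaffected" for m in members):
            members = members + controls
        affected = [m.sample_id for m in members if m.affection == "affected"]
        unaffected = [m.sample_id for m in members if m.affection == "unaffected"]
        states = set()
        for key in matrix.variants:
            if key not in impact_pass:
                continue
            doses_a = [dosage(key, s) for s in affected]
            doses_u = [dosage(key, s) for s in unaffected]
            if config.missing_policy == "exclude_variant":
                if MISSING in doses_a or MISSING in doses_u:
                    continue
            else:
                doses_a = [0 if d == MISSING else d for d in doses_a]
                doses_u = [0 if d == MISSING else d for d in doses_u]
            if any(d != 0 for d in doses_u):
                continue
            if config.zygosity_strict:
                if all(d == 1 for d in doses_a):
                    states.add((key, "het"))
                elif all(d == 2 for d in doses_a):
                    states.add((key, "hom"))
            else:
                if all(d >= 1 for d in doses_a):
                    states.add((key, "het"))
        per_family[fid] = states

    def rare_or_deleterious(key):
        a = ann.get(key)
        maf = a.maf if a else None
        cadd = a.cadd if a else None
        return (maf is None or maf < config.maf_threshold) or (
            cadd is not None and cadd > config.cadd_threshold
        )

    after_freq = {
        fid: {(k, s) for (k, s) in states if rare_or_deleterious(k)}
        for fid, states in per_family.items()
    }

    candidate_keys = {k for states in after_freq.values() for (k, _) in states}
    unaffected_everyone = [
        m.sample_id for m in pedigrees.all_samples() if m.affection == "unaffected"
    ]
    survivors = set()
    for key in candidate_keys:
        if any(dosage(key, s) >= 1 for s in unaffected_everyone):
            continue
        survivors.add(key)

    key_fams = {}
    for fid, states in after_freq.items():
        for (k, _) in states:
            key_fams.setdefault(k, set()).add(fid)
    prioritized = set()
    for key in survivors:
        a = ann.get(key)
        gene = a.gene if a else None
        n_fam = len(key_fams.get(key, set()))
        if (
            n_fam >= config.min_sharing_families
            or gene in inner_ear
            or gene in balance
        ):
            prioritized.add(key)
    return per_family, after_freq, survivors, prioritized
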