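import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famseg.datamodel import (
    GenotypeMatrix,
    PedigreeSet,
    Sample,
    VariantAnnotation,
    VariantKey,
)
from famseg.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_key(pos: int, alt: str = "G") -> VariantKey:
    return VariantKey("chr5", pos, "A", alt)


@pytest.fixture(scope="session")
def small_cohort():
    """Default study conditions at a reduced background size."""
    return simulate_cohort(SimulationConfig(seed=7, n_background_variants=400))


@pytest.fixture(scope="session")
def ideal_cohort():
    """Fully penetrant, noise-free cohort: the planted variant must survive."""
    return simulate_cohort(
        SimulationConfig(
            seed=13, penetrance=1.0, phenocopy_rate=0.0, n_background_variants=300
        )
    )


@pytest.fixture()
def toy_family():
    """Hand-built single family: 2 affected het, 1 affected hom variant etc.

    Variants:
      v1 (pos 100): both affected het, unaffected ref      -> shared het
      v2 (pos 200): affected het + affected hom            -> zygosity conflict
      v3 (pos 300): both affected hom, unaffected ref      -> shared hom
      v4 (pos 400): both affected het, unaffected het      -> unaffected carrier
      v5 (pos 500): affected het + missing call            -> missing policy
    """
    keys = [make_key(p) for p in (100, 200, 300, 400, 500)]
    samples = ["A1", "A2", "U1"]
    dosages = np.array(
        [
            [1, 1, 0],
            [1, 2, 0],
            [2, 2, 0],
            [1, 1, 1],
            [1, -1, 0],
        ],
        dtype=np.int8,
    )
    members = [
        Sample(sample_id="A1", family_id="F1", affection="affected", is_proband=True),
        Sample(sample_id="A2", family_id="F1", affection="affected"),
        Sample(sample_id="U1", family_id="F1", affection="unaffected"),
    ]
    matrix = GenotypeMatrix(variants=keys, samples=samples, dosages=dosages)
    annotations = [VariantAnnotation(key=k, gene=f"G{i}", impact="MODERATE",
                                     maf=0.001, cadd=20.0)
                   for i, k in enumerate(keys)]
    return members, matrix, annotations
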