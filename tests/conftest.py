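import numpy as np
import pytest

import mrdtrack as m


@pytest.fixture
def clone3():
    """A unique-tier disease clone with three tracked rearrangements."""
    return m.gen_malignant_clone(3, seed=2, patient_id="p3")


@pytest.fixture
def profile3(clone3):
    """Tracking profile for clone3 with an allowed-mutation budget of 3."""
    return m.TrackingProfile(
        patient_id=clone3.patient_id,
        tracked=[
            m.TrackedSequence(seq, locus, allowed_mutations=3, uniqueness_score=6.0)
            for locus, seq in clone3.sequences
        ],
    )


@pytest.fixture
def profile3_exact(clone3):
    """Same profile but with zero mutation tolerance (exact matching)."""
    return m.TrackingProfile(
        patient_id=clone3.patient_id,
        tracked=[
            m.TrackedSequence(seq, locus, allowed_mutations=0, uniqueness_score=6.0)
            for locus, seq in clone3.sequences
        ],
    )


@pytest.fixture
def background():
    return m.gen_healthy_repertoire(2000, seed=4, donor_id="bg")


def poisson_samples(clone, expected_cells, n, seed0=0, dna_mass_pg=2e6):
    """Contrived samples with pure Poisson template sampling (no assay noise)."""
    return [
        m.contrive_sample(
            clone, None, dna_mass_pg, expected_cells,
            seed=seed0 + i, sample_id=f"s{i}",
        )
        for i in range(n)
    ]


@pytest.fixture
def make_poisson_samples():
    return poisson_samples


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
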