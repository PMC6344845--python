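import numpy as np
import pytest

from dombind import bindfreq
from dombind.fixtures import FamilySpec, ToyFamily, build_family


def family_alignment(fam: ToyFamily) -> dict[str, str]:
    """Instance-id -> match-state alignment row for a toy family."""
    n = fam.spec.n_states
    rows = {}
    for hit, st, lig in fam.instances:
        iid = bindfreq.instance_key(st, hit, lig)
        rows[iid] = hit.aligned_row(fam.sequences[hit.protein_id], n)
    return rows


@pytest.fixture(scope="session")
def clean_family() -> ToyFamily:
    """Noise-free, mutation-free family: planted truth is exact."""
    return build_family(
        FamilySpec(distance_noise_sd=0.0, mutation_rate=0.0, n_instances=6, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_family() -> ToyFamily:
    """Family with jitter and sequence divergence, defaults otherwise."""
    return build_family(FamilySpec(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
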