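import numpy as np
import pytest

from netgranger import CouplingSpec, Edge, generate_cohort


@pytest.fixture(scope="session")
def attenuated_spec() -> CouplingSpec:
    """6-channel VAR(1) with own-history terms and one cross edge that is
    attenuated in group B."""
    edges = [Edge(i, i, 1, 0.5) for i in range(6)] + [Edge(0, 1, 1, 0.5)]
    return CouplingSpec(
        n_channels=6,
        order=1,
        edges=tuple(edges),
        attenuation={"A": [1.0] * 6 + [1.0], "B": [1.0] * 6 + [0.3]},
    )


@pytest.fixture(scope="session")
def small_cohort(attenuated_spec):
    """A small two-group cohort shared across I/O and pipeline tests."""
    return generate_cohort(attenuated_spec, n_per_group=(4, 5), T=128, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
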