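import numpy as np
import pandas as pd
import pytest

from specrich import AbundanceMatrix


@pytest.fixture
def toy_two_site_matrix() -> AbundanceMatrix:
    """Two sites, five species; site1 = {s1:1, s2:2, s3:3}, site2 = {s2:1, s4:1, s5:2}."""
    frame = pd.DataFrame(
        {"s1": [1, 0], "s2": [2, 1], "s3": [3, 0], "s4": [0, 1], "s5": [0, 2]},
        index=["site1", "site2"],
    )
    return AbundanceMatrix.from_frame(frame)


def random_abundance_matrix(
    rng: np.random.Generator, max_sites: int = 8, max_species: int = 30
) -> AbundanceMatrix:
    """A random sparse abundance matrix with >= 2 non-empty sites."""
    while True:
        n_sites = int(rng.integers(2, max_sites + 1))
        n_species = int(rng.integers(2, max_species + 1))
        counts = (rng.random((n_sites, n_species)) < 0.4) * rng.geometric(
            0.45, size=(n_sites, n_species)
        )
        frame = pd.DataFrame(
            counts,
            index=[f"t{i}" for i in range(n_sites)],
            columns=[f"s{j}" for j in range(n_species)],
        )
        matrix = AbundanceMatrix.from_frame(frame, prune=True)
        if matrix.n_sites >= 2 and matrix.n_species >= 1:
            return matrix
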