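import numpy as np
import pytest

from enzyph import (DEFAULT_GROUPINGS, SyntheticSpec, build_feature_matrix,
                    generate_dataset)

HYDRO = DEFAULT_GROUPINGS[0]  # hydrophobicity: RKEDQN | GASTPHY | CVLIMFW


@pytest.fixture
def hydro_grouping():
    return HYDRO


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def planted_matrix():
    """Feature matrix from the default planted-contrast generator, n=60+60."""
    records = generate_dataset(SyntheticSpec(n_acid=60, n_alkaline=60, seed=11))
    return build_feature_matrix(records)


def random_sequences(rng, n, min_len=2, max_len=50):
    from enzyph import ALPHABET
    out = []
    for _ in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(ALPHABET), size=L)))
    return out
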