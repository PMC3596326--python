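import numpy as np
import pytest

import foldchron as fc


@pytest.fixture(scope="session")
def purine():
    """Packaged purine ages and enzyme network."""
    return fc.load_purine_fixture()


@pytest.fixture
def small_matrix():
    """Tiny hand-written abundance census with a clean age gradient."""
    counts = np.array(
        [
            [9, 8, 9, 7],
            [5, 5, 4, 6],
            [2, 3, 2, 2],
            [1, 1, 0, 1],
            [0, 0, 1, 0],
        ]
    )
    return fc.AbundanceMatrix(
        counts, [f"F{i}" for i in range(1, 6)], [f"P{j}" for j in range(1, 5)]
    )


def random_character_matrix(seed: int, n_taxa: int = 5, n_chars: int = 6) -> fc.CharacterMatrix:
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 24, (n_taxa, n_chars)).astype(np.int16)
    return fc.CharacterMatrix(
        states, [f"T{i}" for i in range(n_taxa)], [f"c{j}" for j in range(n_chars)]
    )
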