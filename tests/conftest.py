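import numpy as np
import pytest

from morphloss import (
    CharacterMatrix,
    SimulationConfig,
    TipStatus,
    assemble_matched_matrix,
    simulate_tree,
)


@pytest.fixture(scope="session")
def small_tree():
    """8-tip tree (4 fossil, 4 extant) used across unit tests."""
    return simulate_tree(
        SimulationConfig(n_extant=4, n_fossil=4, seed=11, max_attempts=20_000)
    )


@pytest.fixture(scope="session")
def study_tree():
    """The study-scale generating tree: 32 fossil + 32 extant tips."""
    return simulate_tree(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def study_matrix(study_tree):
    """64 x 254 homoplasy-matched binary matrix on the study tree."""
    matrix, realized = assemble_matched_matrix(study_tree, SimulationConfig(seed=0))
    matrix.realized_ci_histogram = realized
    return matrix


def random_matrix(
    rng: np.random.Generator,
    n_taxa: int,
    n_chars: int,
    p_missing: float = 0.0,
    n_fossil: int = 0,
) -> CharacterMatrix:
    """Random binary matrix with iid missingness, for oracle comparisons."""
    data = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8)
    if p_missing > 0:
        data[rng.random((n_taxa, n_chars)) < p_missing] = -1
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    status = {
        t: TipStatus.FOSSIL if i < n_fossil else TipStatus.EXTANT
        for i, t in enumerate(taxa)
    }
    return CharacterMatrix(taxa=taxa, data=data, status=status)
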