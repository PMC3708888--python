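import numpy as np
import pytest
from hypothesis import settings

from ccgibbs.dataset import TrainingData
from ccgibbs.groups import GroupIncidence

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def training_data_from_matrices(S: np.ndarray, b: np.ndarray) -> TrainingData:
    """Wrap plain matrices as TrainingData (bypassing the ingest pipeline)."""
    m, n = S.shape
    compounds = [f"C{i:04d}" for i in range(1, m + 1)]
    return TrainingData(
        S=np.asarray(S, dtype=float),
        dG_obs=np.asarray(b, dtype=float),
        weights=np.ones(n),
        compound_index=compounds,
        reaction_index=[("col", j) for j in range(n)],
        replicate_counts=np.ones(n, dtype=int),
        replicate_values=[[float(v)] for v in b],
    )


def incidence_from_matrix(G: np.ndarray, compounds: list[str]) -> GroupIncidence:
    g = G.shape[1]
    return GroupIncidence(
        G=np.asarray(G, dtype=float),
        compound_index=list(compounds),
        group_index=[f"g{j:03d}" for j in range(1, g + 1)],
    )


@pytest.fixture
def small_world():
    """Default-condition synthetic world with one orphan compound."""
    from ccgibbs.synthetic import SimConfig, generate

    return generate(SimConfig(seed=7, n_orphan_compounds=1))
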