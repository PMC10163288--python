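import numpy as np
import pytest

from binderscreen import synth
from binderscreen.structio import ChainStructure, ComplexStructure, ConfidenceBundle


@pytest.fixture
def toy_complex() -> ComplexStructure:
    """A small deterministic binder/target complex (10 + 20 residues)."""
    return synth.make_toy_complex(10, 20, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_bundle(
    rng: np.random.Generator, n_binder: int, n_target: int
) -> ConfidenceBundle:
    """Unstructured random confidence bundle for oracle-equivalence tests."""
    n = n_binder + n_target
    return ConfidenceBundle(
        plddt=rng.uniform(20, 100, size=n),
        pae=rng.uniform(0, 31.75, size=(n, n)),
        chain_map=["A"] * n_binder + ["B"] * n_target,
    )


def simple_chain(chain_id: str, coords) -> ChainStructure:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return ChainStructure(chain_id, np.arange(1, n + 1), ["ALA"] * n, coords)
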