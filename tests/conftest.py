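import numpy as np
import pytest

import rnabackmap as rb


@pytest.fixture(scope="session")
def standard_library() -> rb.TemplateLibrary:
    """k=1 library: only the packaged A-form standard fragments."""
    return rb.TemplateLibrary.standard_only()


@pytest.fixture(scope="session")
def synthetic_library() -> rb.TemplateLibrary:
    """k=6 library selected from synthetic conformer pools (fixed seed)."""
    return rb.make_synthetic_library(6, seed=2024)


@pytest.fixture(scope="session")
def ideal_strand() -> rb.Structure:
    """Clean 12-nt ideal A-form strand covering all four bases."""
    return rb.make_ideal_strand(rb.FixtureSpec(sequence="GACGUAUGCAGG"))


@pytest.fixture()
def strand(ideal_strand) -> rb.Structure:
    """Mutable copy of the session strand."""
    return ideal_strand.copy()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def all_coords(structure: rb.Structure) -> np.ndarray:
    return np.concatenate([res.coords() for res in structure.residues()])
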