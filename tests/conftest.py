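import numpy as np
import pytest

from liunet.model import ArchitectureConfig
from liunet.synthetic import PhantomConfig, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def tiny_arch() -> ArchitectureConfig:
    """Smallest practical depth-5 network; input must be divisible by 16."""
    return ArchitectureConfig.from_widths((4, 8, 16, 32, 32))


@pytest.fixture(scope="session")
def phantom32():
    """One deterministic 32^3 phantom subject."""
    return generate_phantom(PhantomConfig(shape=(32, 32, 32), seed=11), 0)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Three 32^3 phantom subjects on disk in BraTS layout."""
    root = tmp_path_factory.mktemp("cohort")
    generate_cohort(PhantomConfig(shape=(32, 32, 32), n_subjects=3, seed=5), root)
    return root


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
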