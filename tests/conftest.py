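import numpy as np
import pytest

from spinalquant.atlas import build_region_ontology
from spinalquant.phantom import PhantomConfig, deposit_signal, generate_template_phantom


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast phantom grid for unit tests."""
    return PhantomConfig(n_sections=12, ny=96, nx=96)


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    autofluor, annotation = generate_template_phantom(small_cfg, seed=101)
    return autofluor, annotation


@pytest.fixture(scope="session")
def small_signal(small_cfg, small_phantom):
    _, annotation = small_phantom
    return deposit_signal(annotation, small_cfg, seed=202)


@pytest.fixture(scope="session")
def full_ontology():
    return build_region_ontology()
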