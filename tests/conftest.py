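import numpy as np
import pytest

from vte_gxe import GeneratorSpec, default_panel, generate_cohort, make_study_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """Deterministic cohort reproducing the published count tables."""
    return make_study_fixture()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort for plumbing tests (deterministic)."""
    spec = GeneratorSpec()
    spec.n = {"general": 300, "roma": 300}
    return generate_cohort(spec, seed=np.random.default_rng(1234))
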