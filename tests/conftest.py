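import numpy as np
import pytest

from crosspath.io import normalize_log1p_cp10k
from crosspath.pipeline import run_study
from crosspath.simulate import emit_fixture


@pytest.fixture(scope="session")
def tiny_study():
    """Deterministic tiny three-species study with planted truth."""
    return emit_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def tiny_normalized(tiny_study):
    return {
        sp: normalize_log1p_cp10k(m) for sp, m in tiny_study.matrices.items()
    }


@pytest.fixture(scope="session")
def tiny_result(tiny_study):
    return run_study(tiny_study, n_perm=100, min_size=3, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
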