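import numpy as np
import pytest

from plstraj.synthdata import Constituent, SyntheticSpec, corn_like_spec, generate


@pytest.fixture(scope="session")
def clean_rank1_spec():
    """Single constituent, no artifacts: X is exactly rank 1 and y linear in it."""
    return SyntheticSpec(
        axis_start=1100.0,
        axis_step=2.0,
        axis_count=50,
        constituents=(
            Constituent(bands=((1150.0, 20.0, 0.05),), concentration_range=(9.0, 11.0)),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_rank1_ds(clean_rank1_spec):
    return generate(clean_rank1_spec, 30)


@pytest.fixture(scope="session")
def corn_like_ds():
    """The default 60-sample corn-moisture-like scenario with all artifacts."""
    return generate(corn_like_spec(seed=0), 60)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
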