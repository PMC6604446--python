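import numpy as np
import pytest

from masscomp.ieee_words import Precision
from masscomp.synth_fixtures import FixtureSpec, generate_mzxml


@pytest.fixture(scope="session")
def centroid_file() -> bytes:
    return generate_mzxml(FixtureSpec(n_scans=3, scan_kind="centroid", seed=11))


@pytest.fixture(scope="session")
def profile_file() -> bytes:
    return generate_mzxml(
        FixtureSpec(n_scans=1, scan_kind="profile", seed=5)
    )


@pytest.fixture(scope="session")
def double_file() -> bytes:
    return generate_mzxml(
        FixtureSpec(n_scans=2, scan_kind="centroid",
                    precision=Precision.DOUBLE, seed=17)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
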