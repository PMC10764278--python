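import numpy as np
import pytest

from filapoly import FilamentProfile, GeneratorConfig, generate_polymorph_dataset


THREE_ROW_STAR = """\
data_particles

loop_
_rlnMicrographName
_rlnHelicalTubeID
_rlnClassNumber
_rlnCoordinateX
_rlnCoordinateY
m1.mrc 1 2 10.0 20.0
m1.mrc 1 3 30.0 40.0
m2.mrc 1 5 50.0 60.0
"""


@pytest.fixture
def three_row_star(tmp_path):
    """Hand-written fixture: 3 particles, 2 filaments across 2 micrographs."""
    path = tmp_path / "three.star"
    path.write_text(THREE_ROW_STAR)
    return path


@pytest.fixture
def default_dataset():
    """One synthetic dataset at generator defaults, seed 1."""
    config = GeneratorConfig(seed=1)
    records, truth = generate_polymorph_dataset(config)
    return config, records, truth


def make_profile(key, n, dist):
    dist = np.asarray(dist, dtype=float)
    return FilamentProfile(key, n, dist / dist.sum())


@pytest.fixture
def profile_factory():
    return make_profile
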