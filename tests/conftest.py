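import numpy as np
import pytest

from epikit import PhantomSpec, Paradigm, get_preset, SequenceParams, Scheme


@pytest.fixture(scope="session")
def epi64():
    return get_preset("epi64")


@pytest.fixture(scope="session")
def epik96():
    return get_preset("epik96")


@pytest.fixture
def small_epik():
    """12-line, 2-interleave EPIK config for cheap exact checks."""
    return SequenceParams(
        scheme=Scheme.EPIK,
        matrix_py=12,
        fov_mm=100.0,
        te_ms=10.0,
        tr_ms=1000.0,
        echo_spacing_ms=1.0,
        keyhole_fraction=0.5,
        n_interleaves=2,
        t2star_ms=50.0,
    )


@pytest.fixture
def short_paradigm():
    """Block design that fits in a few dozen 2.2 s scans."""
    return Paradigm(fixation_s=8.8, block_s=22.0, n_cycles=2)


@pytest.fixture
def small_phantom_spec(short_paradigm):
    return PhantomSpec(
        shape=(32, 32),
        paradigm=short_paradigm,
        noise_sd=0.02,
        seed=7,
    )


def random_valid_params(rng: np.random.Generator) -> SequenceParams:
    """Draw a random EPIK parameterization satisfying the invariants."""
    n_int = int(rng.integers(1, 5))
    kh_half = int(rng.integers(1, 9))
    per_half = int(rng.integers(0, 7)) * n_int
    matrix = 2 * kh_half + 2 * per_half
    return SequenceParams(
        scheme=Scheme.EPIK,
        matrix_py=matrix,
        fov_mm=float(rng.uniform(100, 300)),
        te_ms=float(rng.uniform(20, 50)),
        tr_ms=float(rng.uniform(500, 3000)),
        echo_spacing_ms=float(rng.uniform(0.3, 1.5)),
        keyhole_fraction=2 * kh_half / matrix,
        n_interleaves=n_int,
        t2star_ms=float(rng.uniform(20, 100)),
    )
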