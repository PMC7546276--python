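import numpy as np
import pytest

from vitapk import (
    AbsorptionParams,
    DispositionParams,
    build_designs,
    compile_dataset,
    default_feline_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def disposition():
    """Published typical disposition values (cats, vitacoxib)."""
    return DispositionParams(CL=0.11, Q=0.52, V1=2.88, V2=0.54)


@pytest.fixture(scope="session")
def absorption():
    return AbsorptionParams(ka=0.13, Tk0=3.76, Fr=0.20, F=0.578)


@pytest.fixture(scope="session")
def generating_model():
    return default_feline_model()


@pytest.fixture(scope="session")
def full_synth():
    """One full six-study synthetic dataset (16 cats), fixed seed."""
    return simulate_dataset(build_designs(), model=default_feline_model(), seed=1)


@pytest.fixture(scope="session")
def full_subjects(full_synth):
    return compile_dataset(full_synth.dataset)


@pytest.fixture(scope="session")
def small_synth():
    """Reduced IV+oral design (4 cats), for fast estimation tests."""
    designs = build_designs({"studies": ["S1", "S2"], "n_subjects": 4})
    return simulate_dataset(designs, model=default_feline_model(), seed=3)


@pytest.fixture(scope="session")
def small_subjects(small_synth):
    return compile_dataset(small_synth.dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
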