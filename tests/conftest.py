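import numpy as np
import pytest

from regimeshift import ScenarioParams, default_params, generate_community


@pytest.fixture(scope="session")
def foy_scale_record():
    """The default Foy-scale synthetic scenario (seed 0) with its truth."""
    return generate_community(default_params(seed=0))


@pytest.fixture(scope="session")
def small_record():
    """A fast small scenario for pipeline-level tests."""
    params = ScenarioParams(
        n_species=20,
        n_steps=120,
        span=1000.0,
        regime1_end=650.0,
        shift_age=300.0,
        seed=5,
    )
    return generate_community(params)


@pytest.fixture()
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "age,Cyclotella,Amphora\n10,40,60\n20,55,45\n30,70,30\n"
    )
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
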