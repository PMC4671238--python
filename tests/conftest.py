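import numpy as np
import pytest
from hypothesis import settings

import probdose as pb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# study-like synthetic conditions used across tests: a chronic-rat-style
# continuous body-weight endpoint and a chronic-mouse-style tumor endpoint
RAT_BW_PARAMS = dict(
    family="exponential", params=[400.0, -0.001, 1.0],
    doses=[0, 12.5, 25, 50, 100, 200], n_per_group=50, cv=0.08,
)
MOUSE_TUMOR_PARAMS = dict(
    family="weibull", params=[0.02, 0.001, 1.2],
    doses=[0, 30, 100, 300], n_per_group=50,
)


@pytest.fixture(scope="session")
def rat_bw_dataset():
    return pb.simulate_continuous_dataset(seed=42, **RAT_BW_PARAMS)


@pytest.fixture(scope="session")
def mouse_tumor_dataset():
    return pb.simulate_quantal_dataset(seed=42, **MOUSE_TUMOR_PARAMS)


@pytest.fixture()
def quantal_csv(tmp_path):
    p = tmp_path / "quantal.csv"
    p.write_text("dose,n,affected\n0,50,1\n10,50,5\n30,50,20\n")
    return p


@pytest.fixture()
def continuous_csv(tmp_path):
    p = tmp_path / "continuous.csv"
    p.write_text(
        "dose,n,mean,sd\n0,10,100,8\n5,10,96,8\n15,10,90,7\n45,10,80,6\n"
    )
    return p
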