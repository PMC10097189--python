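import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from chronoamp import (
    AnalyteSpec,
    BiexpParams,
    CottrellParams,
    ElectrodeSpec,
)

#: Published transient parameter sets (10 mM glucose, 0.1 M NaOH) used as
#: generating truths throughout the suite.
NANOPOROUS_BIEXP = BiexpParams(a1=6.74e-4, a2=0.00339, a3=0.00333, k1=0.363, k2=0.0625)
THERMAL_400C_BIEXP = BiexpParams(a1=3.58e-4, a2=0.00265, a3=0.00119, k1=0.425, k2=0.0586)
THERMAL_300C_B0 = 0.00633
LASER_B0 = 0.00152


@pytest.fixture
def glucose():
    return AnalyteSpec(n=2, D=6.7e-10, c=10.0, name="glucose")


@pytest.fixture
def electrode():
    return ElectrodeSpec(A=1e-4, r=1e-6, N=1, label="nanoporous")


@pytest.fixture
def t_grid():
    return 0.1 + 0.1 * np.arange(1500)


@pytest.fixture
def nanoporous_biexp():
    return NANOPOROUS_BIEXP


@pytest.fixture
def cottrell_300C():
    return CottrellParams(B0=THERMAL_300C_B0)
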