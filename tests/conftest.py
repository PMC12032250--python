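import numpy as np
import pytest

from drivesuite.genetics import (
    Diplotype,
    DriveAllele,
    DriveParams,
    EffectorAllele,
    Sex,
)

W, D, R1, R2 = DriveAllele.W, DriveAllele.D, DriveAllele.R1, DriveAllele.R2
C, E, CR = EffectorAllele.C, EffectorAllele.E, EffectorAllele.CR


@pytest.fixture
def measured_params() -> DriveParams:
    """Transmission rates as measured in the inheritance crosses."""
    return DriveParams(
        homing_female=0.996,
        homing_male=0.971,
        uncut_fraction=0.0,
        functional_fraction=0.1,
    )


@pytest.fixture
def mendelian_params() -> DriveParams:
    return DriveParams.mendelian()


def make_dip(d1, d2, e1=C, e2=C, sex=Sex.FEMALE) -> Diplotype:
    return Diplotype((d1, e1), (d2, e2), sex)
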